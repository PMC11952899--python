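import numpy as np
import pytest

from granulekit import granulerf, seqfeat, synthdata


@pytest.fixture(scope="session")
def tiny_training():
    """Small planted-signal learning set: 60 tier-1 positives + 60 background."""
    config = synthdata.GeneratorConfig(
        n_positives=60, n_background=60, tier_fractions=(1.0, 0.0, 0.0, 0.0), seed=11
    )
    records, labels, tiers = synthdata.generate_proteome(config)
    return records, labels["label"].to_numpy(), tiers


@pytest.fixture(scope="session")
def tiny_model(tiny_training):
    """Forest trained on the tiny learning set (shared across tests)."""
    records, labels, _ = tiny_training
    positives = [r for r, y in zip(records, labels) if y == 1]
    vocab = seqfeat.select_vocabulary(positives, provenance="tiny")
    table = seqfeat.build_feature_table(records, vocab)
    return granulerf.train_full(table, labels, vocab, seed=11, n_estimators=100)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_sequence(rng, length):
    return "".join(rng.choice(list(seqfeat.ALPHABET), size=length))
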