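"""Unit and property tests for the sequence feature layer."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulekit import seqfeat
from granulekit.seqfeat import (
    ALPHABET,
    KmerVocabulary,
    ProteinRecord,
    build_feature_table,
    compute_gravy,
    compute_lcr_fraction,
    compute_pI,
    compute_physchem,
    kmer_fractions,
    net_charge,
    read_fasta,
    select_kmer_vocabulary,
    select_vocabulary,
)

sequences = st.text(alphabet=ALPHABET, min_size=1, max_size=500)


# ---------------------------------------------------------------- FASTA I/O

def test_read_fasta_uniprot_header(tmp_path):
    path = tmp_path / "a.fa"
    path.write_text(">sp|P1|X some description\nMKR\n")
    records = read_fasta(path)
    assert [(r.accession, r.sequence) for r in records] == [("P1", "MKR")]


def test_read_fasta_map_policy_substitutes_and_strips(tmp_path):
    path = tmp_path / "a.fa"
    path.write_text(">a\nMU*R\n")
    with pytest.warns(UserWarning):
        records = read_fasta(path, sanitize_policy="map")
    assert records[0].sequence == "MCR"


def test_read_fasta_duplicate_accession_errors(tmp_path):
    path = tmp_path / "a.fa"
    path.write_text(">x\nMK\n>x\nMR\n")
    with pytest.raises(ValueError, match="x"):
        read_fasta(path)


def test_read_fasta_empty_file_errors(tmp_path):
    path = tmp_path / "a.fa"
    path.write_text("")
    with pytest.raises(ValueError):
        read_fasta(path)


def test_read_fasta_drop_protein_policy(tmp_path):
    path = tmp_path / "a.fa"
    path.write_text(">keep\nMKR\n>drop\nMXR\n")
    with pytest.warns(UserWarning):
        records = read_fasta(path, sanitize_policy="drop-protein")
    assert [r.accession for r in records] == ["keep"]


# ------------------------------------------------------------------- GRAVY

@pytest.mark.parametrize(
    "seq,expected",
    [("KK", -3.9), ("AILV", (1.8 + 4.5 + 3.8 + 4.2) / 4)],
)
def test_gravy_examples(seq, expected):
    assert compute_gravy(seq) == pytest.approx(expected)


def test_gravy_single_residue_is_scale_value():
    from Bio.SeqUtils.ProtParamData import kd

    for aa in ALPHABET:
        assert compute_gravy(aa) == kd[aa]


# ---------------------------------------------------------------------- pI

def _grid_search_pI(seq):
    grid = np.linspace(0, 14, 14001)
    charges = np.array([net_charge(seq, ph) for ph in grid])
    return grid[np.argmin(np.abs(charges))]


@pytest.mark.parametrize("seq", ["G", "EEEEEEEE", "KKKKK", "MKRDECY"])
def test_pI_matches_grid_search_oracle(seq):
    assert compute_pI(seq) == pytest.approx(_grid_search_pI(seq), abs=0.01)


def test_pI_glycine_near_neutral_and_acidic_polymer():
    assert 5.5 < compute_pI("G") < 6.5
    assert compute_pI("EEEEEEEE") < 4.5


def test_pI_zero_net_charge_at_solution():
    for seq in ["MKR", "DDEE", "ACDEFGHIKLMNPQRSTVWY"]:
        assert abs(net_charge(seq, compute_pI(seq))) < 1e-5


def test_pI_monotone_in_charged_appendages():
    base = "MGAV"
    pis = [compute_pI(base + "K" * i) for i in range(5)]
    assert all(a <= b + 1e-9 for a, b in zip(pis, pis[1:]))
    pis = [compute_pI(base + "E" * i) for i in range(5)]
    assert all(a >= b - 1e-9 for a, b in zip(pis, pis[1:]))


# --------------------------------------------------------------------- LCR

def test_lcr_homopolymer_is_one():
    assert compute_lcr_fraction("A" * 50) == 1.0


def test_lcr_all_distinct_window_is_zero():
    assert compute_lcr_fraction("ACDEFGHIKLMNPQRSTVWY", window=12) == 0.0


def _brute_force_lcr(seq, window=12, threshold=2.2):
    L = len(seq)
    if L <= window:
        counts = Counter(seq)
        h = -sum(c / L * math.log2(c / L) for c in counts.values())
        return 1.0 if h < threshold else 0.0
    flagged = [False] * L
    for start in range(L - window + 1):
        counts = Counter(seq[start : start + window])
        h = -sum(c / window * math.log2(c / window) for c in counts.values())
        if h < threshold:
            for i in range(start, start + window):
                flagged[i] = True
    return sum(flagged) / L


def test_lcr_matches_brute_force_on_biased_sequences(rng):
    # biased alphabet so low-complexity windows actually occur
    for _ in range(30):
        L = int(rng.integers(5, 300))
        seq = "".join(rng.choice(list("AGSPQRL"), size=L, p=[0.4, 0.3, 0.1, 0.05, 0.05, 0.05, 0.05]))
        assert compute_lcr_fraction(seq) == pytest.approx(_brute_force_lcr(seq))


def test_lcr_window_too_small_errors():
    with pytest.raises(ValueError):
        compute_lcr_fraction("MKRA", window=1)


# --------------------------------------------------------------- physchem

def test_physchem_has_19_named_entries():
    vec = compute_physchem(ProteinRecord("p", "MKR"))
    assert tuple(vec) == seqfeat.PHYSCHEM_FEATURE_NAMES
    assert vec["length"] == 3


def test_molecular_weight_monotone_in_extension():
    base = "MKRDE"
    mw = compute_physchem(ProteinRecord("p", base))["molecular_weight"]
    mw2 = compute_physchem(ProteinRecord("p", base + "A"))["molecular_weight"]
    assert mw2 > mw


# ------------------------------------------------------------------ k-mers

def test_vocabulary_selection_counts_and_ties():
    positives = [ProteinRecord("a", "RGRG"), ProteinRecord("b", "GGGG")]
    # counts: GG=3, RG=2, GR=1
    assert select_kmer_vocabulary(positives, k=2, top_n=2) == ["GG", "RG"]


def test_vocabulary_tie_breaks_alphabetically():
    positives = [ProteinRecord("a", "ACAC"), ProteinRecord("b", "CACA")]
    # AC=2+1, CA=1+2 -> tie at 3, alphabetical
    assert select_kmer_vocabulary(positives, k=2, top_n=2) == ["AC", "CA"]


def test_vocabulary_truncation_warns():
    positives = [ProteinRecord("a", "MK")]
    with pytest.warns(UserWarning):
        vocab = select_kmer_vocabulary(positives, k=2, top_n=50)
    assert vocab == ["MK"]


def test_vocabulary_rejects_too_short_sequences():
    with pytest.raises(ValueError):
        select_kmer_vocabulary([ProteinRecord("a", "MK")], k=3)


def test_kmer_fraction_overlapping_counts():
    got = kmer_fractions("RGGRGG", ["RG", "GG", "GR"])
    assert got == pytest.approx([2 / 5, 2 / 5, 1 / 5])


def test_kmer_fraction_short_sequence_is_zero():
    assert kmer_fractions("RG", ["RGG"]).tolist() == [0.0]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seq=sequences, kmer=st.text(alphabet=ALPHABET, min_size=2, max_size=3))
def test_kmer_fraction_matches_naive_scan(seq, kmer):
    k = len(kmer)
    naive = sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer)
    windows = max(len(seq) - k + 1, 0)
    expected = naive / windows if windows else 0.0
    assert kmer_fractions(seq, [kmer])[0] == pytest.approx(expected)
    assert 0.0 <= expected <= 1.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seq=sequences)
def test_gravy_and_composition_match_naive(seq):
    from Bio.SeqUtils.ProtParamData import kd

    assert compute_gravy(seq) == pytest.approx(
        sum(kd[a] for a in seq) / len(seq)
    )
    comp = seqfeat.composition_fractions(seq)
    assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)
    counts = Counter(seq)
    assert comp[f"comp_{seq[0]}"] == pytest.approx(counts[seq[0]] / len(seq))


# ----------------------------------------------------------- feature table

@pytest.fixture(scope="module")
def small_vocab():
    positives = [
        ProteinRecord("v1", "RGGRGGSRGGY" * 6),
        ProteinRecord("v2", "MKAVLDERGGA" * 6),
    ]
    return select_vocabulary(positives, top_n=50)


def test_feature_table_properties(small_vocab, rng):
    records = [
        ProteinRecord(f"r{i}", "".join(rng.choice(list(ALPHABET), size=80)))
        for i in range(3)
    ]
    table = build_feature_table(records, small_vocab)
    assert table.shape == (3, 19 + 20 + len(small_vocab.k2) + len(small_vocab.k3))
    comp_cols = [c for c in table.columns if c.startswith("comp_")]
    assert np.allclose(table[comp_cols].sum(axis=1), 1.0, atol=1e-9)
    kmer_cols = [c for c in table.columns if c.startswith(("k2_", "k3_"))]
    assert ((table[kmer_cols] >= 0) & (table[kmer_cols] <= 1)).all().all()


def test_feature_table_permutation_equivariant(small_vocab, rng):
    records = [
        ProteinRecord(f"r{i}", "".join(rng.choice(list(ALPHABET), size=60)))
        for i in range(5)
    ]
    table = build_feature_table(records, small_vocab)
    shuffled = build_feature_table(records[::-1], small_vocab)
    assert (shuffled.loc[table.index].to_numpy() == table.to_numpy()).all()


def test_feature_table_deterministic(small_vocab):
    records = [ProteinRecord("a", "MKRDEAGSRGG" * 10)]
    t1 = build_feature_table(records, small_vocab)
    t2 = build_feature_table(records, small_vocab)
    assert (t1.to_numpy() == t2.to_numpy()).all()


def test_vocabulary_tsv_roundtrip(small_vocab, tmp_path):
    path = tmp_path / "vocab.tsv"
    small_vocab.save_tsv(path)
    loaded = KmerVocabulary.load_tsv(path)
    assert loaded.k2 == small_vocab.k2 and loaded.k3 == small_vocab.k3
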