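"""Balanced learning-set assembly from a tier-annotated granule catalogue.

Positive sets come from a tier table (accession, granule_type, tier 1-4,
strongest evidence first); the negative class is drawn uniformly from
the background proteome after excluding every catalogued candidate of
any tier and any granule type, so that weaker-evidence candidates can
later be scored as prediction targets rather than contaminating the
negative class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqfeat import ProteinRecord

GRANULE_TYPES = ("SG", "PB", "PBSG")
TIER_RULES = {"==1": (1,), "<=2": (1, 2), "<=3": (1, 2, 3), "<=4": (1, 2, 3, 4)}


@dataclass
class LearningSet:
    positives: list[str]
    negatives: list[str]
    granule_type: str
    tier_rule: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("learning set must be balanced")
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives overlap")

    @property
    def accessions(self) -> list[str]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [0] * len(self.negatives))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accession": self.accessions, "label": self.labels, "role": "train"}
        )

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_tier_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"accession", "granule_type", "tier"} - set(table.columns)
    if missing:
        raise ValueError(f"tier table missing columns {sorted(missing)}")
    return validate_tier_table(table)


def validate_tier_table(table: pd.DataFrame) -> pd.DataFrame:
    if not table["tier"].isin([1, 2, 3, 4]).all():
        raise ValueError("tiers must be integers 1-4")
    if table.duplicated(["accession", "granule_type"]).any():
        raise ValueError("duplicate (accession, granule_type) rows")
    return table


def filter_by_tier(
    table: pd.DataFrame, granule_type: str, tier_rule: str
) -> list[str]:
    """Accessions of a granule type meeting a tier rule, input order kept.

    ``PBSG`` is the union of the SG and PB catalogues at the stated rule
    (plus any rows already annotated PBSG), deduplicated.
    """
    if granule_type not in GRANULE_TYPES:
        raise ValueError(f"unknown granule_type {granule_type!r}")
    if tier_rule not in TIER_RULES:
        raise ValueError(f"unknown tier_rule {tier_rule!r}")
    tiers = TIER_RULES[tier_rule]
    if granule_type == "PBSG":
        type_mask = table["granule_type"].isin(("SG", "PB", "PBSG"))
    else:
        type_mask = table["granule_type"] == granule_type
    hits = table.loc[type_mask & table["tier"].isin(tiers), "accession"]
    return list(dict.fromkeys(hits))


def sample_negatives(
    proteome_accessions: Sequence[str],
    exclusion: Iterable[str],
    n: int,
    seed: int,
) -> list[str]:
    """Draw n distinct background accessions outside the exclusion set."""
    exclusion = set(exclusion)
    pool = [a for a in proteome_accessions if a not in exclusion]
    if len(pool) < n:
        raise ValueError(
            f"negative pool has {len(pool)} accessions, {n} requested "
            f"(deficit {n - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def assemble_learning_set(
    table: pd.DataFrame,
    proteome: Sequence[ProteinRecord],
    granule_type: str,
    tier_rule: str,
    seed: int,
) -> LearningSet:
    """Balanced positives/negatives for one granule type and tier rule.

    Negatives are sampled from the proteome minus *every* catalogued
    accession (any tier, any type). Positives without a sequence in the
    proteome are dropped with a warning before balancing.
    """
    validate_tier_table(table)
    positives = filter_by_tier(table, granule_type, tier_rule)
    available = {rec.accession for rec in proteome}
    kept = [a for a in positives if a in available]
    dropped = len(positives) - len(kept)
    if dropped:
        warnings.warn(f"{dropped} positives lack a proteome sequence; dropped")
    if not kept:
        raise ValueError("no positives with sequences available")
    exclusion = set(table["accession"])
    negatives = sample_negatives(
        [rec.accession for rec in proteome], exclusion, len(kept), seed
    )
    return LearningSet(
        positives=kept,
        negatives=negatives,
        granule_type=granule_type,
        tier_rule=tier_rule,
        seed=seed,
    )
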