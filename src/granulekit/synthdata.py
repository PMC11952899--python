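"""Synthetic proteomes, tier tables and PPI edge lists for benchmarking.

The generator emulates the statistical structure the prediction method
assumes: granule-like positives carry a compositional signal (RGG-motif
insertions, a hydrophilic GRAVY shift, one planted low-complexity
stretch, cysteine depletion) on top of a human-proteome-like residue
background; tiers carry the same signal at decaying strength, mirroring
decreasing evidence confidence; and the PPI generator is a stochastic
block model whose edge density can be coupled to node propensity, so
that high-propensity proteins concentrate in dense "core" communities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .seqfeat import ALPHABET, ProteinRecord

# Human-proteome-like amino-acid frequencies (average composition of
# reviewed human sequences, percent, renormalized below).
_HUMAN_LIKE_FREQ = {
    "A": 7.01, "R": 5.64, "N": 3.59, "D": 4.74, "C": 2.30,
    "Q": 4.77, "E": 7.10, "G": 6.58, "H": 2.63, "I": 4.34,
    "L": 9.97, "K": 5.72, "M": 2.13, "F": 3.65, "P": 6.31,
    "S": 8.33, "T": 5.36, "W": 1.22, "Y": 2.66, "V": 5.96,
}

_AA = np.array(list(ALPHABET))
_KD = np.array([_KYTE_DOOLITTLE[a] for a in ALPHABET])
_BASE_FREQ = np.array([_HUMAN_LIKE_FREQ[a] for a in ALPHABET])
_BASE_FREQ = _BASE_FREQ / _BASE_FREQ.sum()

# Residues used for planted low-complexity stretches (polar/flexible,
# as in natural LCRs).
_LCR_PRIMARY = "SGQNP"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic proteome and PPI generators.

    Defaults define the benchmark conditions: log-normal lengths
    (median 400 residues, sigma 0.5), RGG insertions at 1.5 motifs per
    100 residues, a GRAVY shift from the -0.2 background toward -0.6,
    one 20-60 residue low-complexity stretch with probability 0.8,
    cysteine frequency scaled by 0.4, and tier signal multipliers
    1.0/0.75/0.5/0.25 for tiers 1-4. The SBM defaults (3 blocks,
    p_in 0.3, p_out 0.01) are the planted-community benchmark.
    """

    n_positives: int = 400
    n_background: int = 2000
    length_median: float = 400.0
    length_sigma: float = 0.5
    min_length: int = 50
    rgg_per_100: float = 1.5
    gravy_background: float = -0.2
    gravy_positive: float = -0.6
    lcr_prob: float = 0.8
    lcr_len_range: tuple[int, int] = (20, 60)
    cys_factor: float = 0.4
    tier_decay: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25)
    tier_fractions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    granule_type: str = "PBSG"
    sbm_blocks: int = 3
    sbm_p_in: float = 0.3
    sbm_p_out: float = 0.01
    sbm_coupling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lcr_prob", "sbm_p_in", "sbm_p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cys_factor < 0 or self.cys_factor * _HUMAN_LIKE_FREQ["C"] > 100:
            raise ValueError(f"infeasible cys_factor {self.cys_factor}")
        if self.min_length < 50:
            raise ValueError("min_length must be >= 50")
        if len(self.tier_decay) != 4 or len(self.tier_fractions) != 4:
            raise ValueError("tier_decay and tier_fractions need 4 entries")
        if abs(sum(self.tier_fractions) - 1.0) > 1e-9:
            raise ValueError("tier_fractions must sum to 1")
        if self.sbm_p_in < self.sbm_p_out:
            warnings.warn("p_in < p_out: anti-community regime")


def _tilted_frequencies(target_gravy: float, cys_factor: float = 1.0) -> np.ndarray:
    """Residue frequencies exponentially tilted to a target mean GRAVY.

    Solves f_beta ∝ f * exp(beta * kd) for the beta whose expected
    hydropathy matches *target_gravy* (bisection; the mean is strictly
    increasing in beta), then rescales cysteine and renormalizes.
    """

    def mean_gravy(beta: float) -> float:
        w = _BASE_FREQ * np.exp(beta * _KD)
        w /= w.sum()
        return float(w @ _KD)

    lo, hi = -5.0, 5.0
    if not mean_gravy(lo) <= target_gravy <= mean_gravy(hi):
        raise ValueError(f"target GRAVY {target_gravy} out of reachable range")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_gravy(mid) < target_gravy:
            lo = mid
        else:
            hi = mid
    beta = 0.5 * (lo + hi)
    freq = _BASE_FREQ * np.exp(beta * _KD)
    freq /= freq.sum()
    freq[ALPHABET.index("C")] *= cys_factor
    return freq / freq.sum()


def _draw_length(rng: np.random.Generator, config: GeneratorConfig) -> int:
    L = int(round(rng.lognormal(math.log(config.length_median), config.length_sigma)))
    return max(L, config.min_length)


def _draw_sequence(rng: np.random.Generator, length: int, freq: np.ndarray) -> list[str]:
    return list(rng.choice(_AA, size=length, p=freq))


def _plant_lcr(rng: np.random.Generator, seq: list[str], config: GeneratorConfig) -> None:
    lo, hi = config.lcr_len_range
    length = int(rng.integers(lo, hi + 1))
    if len(seq) <= length + 2:
        return
    start = int(rng.integers(0, len(seq) - length))
    primary = str(rng.choice(list(_LCR_PRIMARY)))
    secondary = "G" if primary != "G" else "S"
    stretch = rng.choice([primary, secondary], size=length, p=[0.85, 0.15])
    seq[start : start + length] = list(stretch)


def _plant_rgg(
    rng: np.random.Generator, seq: list[str], rate_per_100: float
) -> None:
    if rate_per_100 <= 0 or len(seq) < 4:
        return
    k = rng.poisson(len(seq) / 100.0 * rate_per_100)
    for _ in range(k):
        pos = int(rng.integers(0, len(seq) - 3))
        seq[pos : pos + 3] = ["R", "G", "G"]


def _positive_sequence(
    rng: np.random.Generator, config: GeneratorConfig, decay: float
) -> str:
    target = config.gravy_background + decay * (
        config.gravy_positive - config.gravy_background
    )
    cys = 1.0 - decay * (1.0 - config.cys_factor)
    freq = _tilted_frequencies(target, cys)
    seq = _draw_sequence(rng, _draw_length(rng, config), freq)
    if rng.random() < config.lcr_prob * decay:
        _plant_lcr(rng, seq, config)
    _plant_rgg(rng, seq, config.rgg_per_100 * decay)
    return "".join(seq)


def generate_proteome(
    config: GeneratorConfig,
) -> tuple[list[ProteinRecord], pd.DataFrame, pd.DataFrame]:
    """Synthetic proteome with planted granule signal.

    Returns ``(records, label_table, tier_table)``: positives first
    (accessions ``POS0001``...), then background (``BG0001``...). The
    label table has columns accession/label (1 positive, 0 background);
    the tier table covers positives only, tiers assigned by
    ``tier_fractions`` with signal scaled by ``tier_decay``.
    """
    rng = np.random.default_rng(config.seed)
    background_freq = _tilted_frequencies(config.gravy_background)
    counts = np.floor(
        np.asarray(config.tier_fractions) * config.n_positives
    ).astype(int)
    counts[0] += config.n_positives - counts.sum()
    records: list[ProteinRecord] = []
    tier_rows = []
    i = 0
    for tier, (count, decay) in enumerate(zip(counts, config.tier_decay), start=1):
        for _ in range(count):
            i += 1
            acc = f"POS{i:04d}"
            records.append(ProteinRecord(acc, _positive_sequence(rng, config, decay)))
            tier_rows.append(
                {"accession": acc, "granule_type": config.granule_type, "tier": tier}
            )
    for j in range(1, config.n_background + 1):
        seq = _draw_sequence(rng, _draw_length(rng, config), background_freq)
        records.append(ProteinRecord(f"BG{j:04d}", "".join(seq)))
    labels = pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "label": [1] * config.n_positives + [0] * config.n_background,
        }
    )
    return records, labels, pd.DataFrame(tier_rows)


def generate_chimera(
    config: GeneratorConfig, segment_length: int = 150, seed: int | None = None
) -> tuple[ProteinRecord, tuple[int, int]]:
    """One background protein with a planted granule-like segment.

    The segment (full-strength positive composition with RGG insertions
    and a forced low-complexity stretch) is placed at a random interior
    position; its 0-based half-open span is returned for test surfaces
    that check peak localization.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    total = max(_draw_length(rng, config), segment_length + 100)
    if segment_length >= total:
        raise ValueError("segment_length must be smaller than total length")
    background_freq = _tilted_frequencies(config.gravy_background)
    seq = _draw_sequence(rng, total, background_freq)
    positive_freq = _tilted_frequencies(config.gravy_positive, config.cys_factor)
    segment = _draw_sequence(rng, segment_length, positive_freq)
    _plant_lcr(rng, segment, config)
    _plant_rgg(rng, segment, config.rgg_per_100)
    start = int(rng.integers(20, total - segment_length - 20))
    seq[start : start + segment_length] = segment
    return ProteinRecord("CHIMERA", "".join(seq)), (start, start + segment_length)


def generate_ppi(
    config: GeneratorConfig,
    propensity: pd.Series | pd.DataFrame | dict,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Propensity-coupled stochastic-block-model PPI edge list.

    Nodes are ranked by propensity and split into ``sbm_blocks``
    contiguous blocks (block 0 = highest propensity). The probability of
    an edge is the block base rate (p_in within, p_out between) times
    ``((p_i * p_j) / 0.75**2) ** sbm_coupling``, so expected degree
    increases with propensity when coupling > 0; coupling 0 recovers the
    plain SBM. Combined scores are uniform integers in [400, 999].

    Returns the edge table (protein1, protein2, combined_score) and the
    node -> block assignment.
    """
    if isinstance(propensity, pd.DataFrame):
        p = propensity["p"]
    else:
        p = pd.Series(propensity, dtype=float)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    order = p.sort_values(ascending=False, kind="mergesort").index
    n = len(order)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    bounds = np.linspace(0, n, config.sbm_blocks + 1).astype(int)
    blocks = {}
    for b in range(config.sbm_blocks):
        for node in order[bounds[b] : bounds[b + 1]]:
            blocks[node] = b
    nodes = list(order)
    block_vec = np.array([blocks[v] for v in nodes])
    base = np.where(
        block_vec[:, None] == block_vec[None, :], config.sbm_p_in, config.sbm_p_out
    )
    factor = (p.loc[nodes].to_numpy() / 0.75) ** config.sbm_coupling
    prob = np.clip(base * factor[:, None] * factor[None, :], 0.0, 1.0)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    ii, jj = np.nonzero(upper)
    scores = rng.integers(400, 1000, size=len(ii))
    edges = pd.DataFrame(
        {
            "protein1": [nodes[i] for i in ii],
            "protein2": [nodes[j] for j in jj],
            "combined_score": scores,
        }
    )
    return edges, blocks


def synthetic_propensities(
    n: int, seed: int = 0, prefix: str = "SIM"
) -> pd.DataFrame:
    """Uniform propensities on [0.5, 1] for standalone network benchmarks."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.5, 1.0, size=n)
    return pd.DataFrame(
        {"p": p}, index=[f"{prefix}{i:04d}" for i in range(1, n + 1)]
    )
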