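"""Sequence-derived features for RNA-granule propensity models.

Each protein is represented by 139 numbers: 19 physicochemical
descriptors, 20 amino-acid composition fractions, and occurrence
fractions over a data-driven vocabulary of the 50 most abundant 2-mers
and 50 most abundant 3-mers of the positive (granule) training set.
The k-mer block captures local grammar such as the RGG/RG motifs that
are enriched in granule-protein disordered regions; the physicochemical
block covers the global hydropathy / charge / low-complexity axes that
separate granule proteins from the proteome background.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import Flex as _VIHINEN_FLEX
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

# Conservative substitutions for ambiguity codes under the "map" policy;
# every other non-canonical symbol (X, J, O, gaps, stops) is dropped.
_MAP_SUBSTITUTIONS = {"U": "C", "B": "D", "Z": "E"}

SANITIZE_POLICIES = ("map", "drop-residue", "drop-protein")

#: Canonical order of the 19 physicochemical descriptors.
PHYSCHEM_FEATURE_NAMES = (
    "length",
    "molecular_weight",
    "isoelectric_point",
    "gravy",
    "lcr_fraction",
    "aromaticity",
    "net_charge_ph7",
    "positive_fraction",
    "negative_fraction",
    "charged_fraction",
    "charge_asymmetry",
    "polar_fraction",
    "tiny_fraction",
    "proline_fraction",
    "glycine_fraction",
    "cysteine_fraction",
    "serine_fraction",
    "mean_flexibility",
    "max_run_fraction",
)

COMPOSITION_FEATURE_NAMES = tuple(f"comp_{aa}" for aa in ALPHABET)

# EMBOSS pKa set used for the charge model behind the isoelectric point.
_PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
_PKA_NTERM = 8.6
_PKA_CTERM = 3.6


@dataclass(frozen=True)
class ProteinRecord:
    """One accession plus a sanitized amino-acid sequence."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"{self.accession}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _accession_from_header(header: str) -> str:
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def _sanitize(seq: str, policy: str, accession: str) -> str | None:
    """Return a canonical-alphabet sequence, or None to drop the protein."""
    seq = seq.upper()
    if set(seq) <= _ALPHABET_SET:
        return seq
    if policy == "drop-protein":
        warnings.warn(f"{accession}: dropped (non-canonical residues)")
        return None
    out = []
    for ch in seq:
        if ch in _ALPHABET_SET:
            out.append(ch)
        elif policy == "map" and ch in _MAP_SUBSTITUTIONS:
            out.append(_MAP_SUBSTITUTIONS[ch])
        # else: dropped residue
    warnings.warn(f"{accession}: non-canonical residues handled by {policy!r}")
    return "".join(out)


def read_fasta(path: str | Path, sanitize_policy: str = "map") -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The accession is the first whitespace-delimited header token, with
    UniProt ``sp|ACC|NAME`` headers reduced to ``ACC``. Non-canonical
    letters are handled per *sanitize_policy*: ``map`` (U->C, B->D,
    Z->E, others dropped), ``drop-residue`` or ``drop-protein``.
    Zero-length sequences after sanitization are dropped with a warning;
    duplicate accessions are an error.
    """
    if sanitize_policy not in SANITIZE_POLICIES:
        raise ValueError(f"unknown sanitize_policy {sanitize_policy!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(entry.description or entry.id)
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seq = _sanitize(str(entry.seq), sanitize_policy, acc)
        if seq is None:
            continue
        if not seq:
            warnings.warn(f"{acc}: empty after sanitization, dropped")
            continue
        seen.add(acc)
        records.append(ProteinRecord(acc, seq))
    if not records and not seen:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# physicochemical descriptors
# ---------------------------------------------------------------------------

def compute_gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(_KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a pH (EMBOSS pKa set)."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence)
    positive = 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
    for aa, pka in _PKA_POSITIVE.items():
        positive += counts[aa] / (1.0 + 10 ** (ph - pka))
    negative = 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    for aa, pka in _PKA_NEGATIVE.items():
        negative += counts[aa] / (1.0 + 10 ** (pka - ph))
    return positive - negative


def compute_pI(sequence: str, tol: float = 1e-6) -> float:
    """Isoelectric point: pH of zero modeled net charge, by bisection.

    Net charge is strictly decreasing in pH, so bisection on [0, 14]
    converges; iteration stops when |charge| < *tol*.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _window_entropy(counts: Counter, window: int) -> float:
    h = 0.0
    for c in counts.values():
        if c:
            p = c / window
            h -= p * math.log2(p)
    return h


def compute_lcr_fraction(
    sequence: str, window: int = 12, entropy_threshold: float = 2.2
) -> float:
    """Fraction of residues inside low-complexity regions.

    A sliding window is low-complexity when its Shannon entropy (bits,
    over residue frequencies) falls below *entropy_threshold*; a residue
    counts as LCR when covered by at least one such window. Sequences
    shorter than the window are scored as a single whole-sequence window.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not sequence:
        raise ValueError("empty sequence")
    L = len(sequence)
    if L <= window:
        counts = Counter(sequence)
        return 1.0 if _window_entropy(counts, L) < entropy_threshold else 0.0
    flagged = np.zeros(L, dtype=bool)
    counts = Counter(sequence[:window])
    for start in range(L - window + 1):
        if start:
            out_aa = sequence[start - 1]
            counts[out_aa] -= 1
            counts[sequence[start + window - 1]] += 1
        if _window_entropy(counts, window) < entropy_threshold:
            flagged[start : start + window] = True
    return float(flagged.mean())


def _max_run_length(sequence: str) -> int:
    best = run = 1
    for prev, cur in zip(sequence, sequence[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def compute_physchem(
    record: ProteinRecord,
    lcr_window: int = 12,
    lcr_entropy_threshold: float = 2.2,
) -> dict[str, float]:
    """All 19 physicochemical descriptors, in canonical order."""
    seq = record.sequence
    L = len(seq)
    counts = Counter(seq)
    frac = lambda letters: sum(counts[a] for a in letters) / L
    pos, neg = frac("KR"), frac("DE")
    values = {
        "length": float(L),
        "molecular_weight": ProteinAnalysis(seq).molecular_weight(),
        "isoelectric_point": compute_pI(seq),
        "gravy": compute_gravy(seq),
        "lcr_fraction": compute_lcr_fraction(seq, lcr_window, lcr_entropy_threshold),
        "aromaticity": frac("FWY"),
        "net_charge_ph7": net_charge(seq, 7.0),
        "positive_fraction": pos,
        "negative_fraction": neg,
        "charged_fraction": pos + neg,
        "charge_asymmetry": pos - neg,
        "polar_fraction": frac("STNQCY"),
        "tiny_fraction": frac("AGS"),
        "proline_fraction": frac("P"),
        "glycine_fraction": frac("G"),
        "cysteine_fraction": frac("C"),
        "serine_fraction": frac("S"),
        "mean_flexibility": sum(_VIHINEN_FLEX[aa] for aa in seq) / L,
        "max_run_fraction": _max_run_length(seq) / L,
    }
    assert tuple(values) == PHYSCHEM_FEATURE_NAMES
    return values


def composition_fractions(sequence: str) -> dict[str, float]:
    L = len(sequence)
    counts = Counter(sequence)
    return {f"comp_{aa}": counts[aa] / L for aa in ALPHABET}


# ---------------------------------------------------------------------------
# k-mer vocabulary and fractions
# ---------------------------------------------------------------------------

def kmer_counts(sequence: str, k: int) -> Counter:
    """Overlapping k-mer occurrence counts of one sequence."""
    return Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def select_kmer_vocabulary(
    positives: Sequence[ProteinRecord], k: int, top_n: int = 50
) -> list[str]:
    """Top *top_n* k-mers by total overlapping count over the positives.

    Ties break alphabetically so selection is deterministic. When fewer
    than *top_n* distinct k-mers exist, all observed k-mers are returned
    with a warning.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if not positives:
        raise ValueError("positives must be nonempty")
    total: Counter = Counter()
    for rec in positives:
        total.update(kmer_counts(rec.sequence, k))
    if not total:
        raise ValueError(f"no sequence of length >= {k}")
    ranked = sorted(total.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < top_n:
        warnings.warn(
            f"only {len(ranked)} distinct {k}-mers observed (requested {top_n})"
        )
    return [kmer for kmer, _ in ranked[:top_n]]


@dataclass
class KmerVocabulary:
    """Ordered 2-mer and 3-mer vocabularies with selection provenance."""

    k2: list[str]
    k3: list[str]
    provenance: str = ""
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, vocab in ((2, self.k2), (3, self.k3)):
            if len(set(vocab)) != len(vocab):
                raise ValueError(f"duplicate {k}-mers in vocabulary")
            for m in vocab:
                if len(m) != k or set(m) - _ALPHABET_SET:
                    raise ValueError(f"invalid {k}-mer {m!r}")

    @property
    def columns(self) -> list[str]:
        return [f"k2_{m}" for m in self.k2] + [f"k3_{m}" for m in self.k3]

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\ttotal_count\n")
            for m in self.k2 + self.k3:
                fh.write(f"{m}\t{self.counts.get(m, 0)}\n")

    @classmethod
    def load_tsv(cls, path: str | Path, provenance: str = "") -> "KmerVocabulary":
        df = pd.read_csv(path, sep="\t")
        k2 = [m for m in df["kmer"] if len(m) == 2]
        k3 = [m for m in df["kmer"] if len(m) == 3]
        counts = dict(zip(df["kmer"], df["total_count"]))
        return cls(k2=k2, k3=k3, provenance=provenance or str(path), counts=counts)


def select_vocabulary(
    positives: Sequence[ProteinRecord], top_n: int = 50, provenance: str = ""
) -> KmerVocabulary:
    """Select the 2-mer and 3-mer vocabularies from the positive set."""
    k2 = select_kmer_vocabulary(positives, 2, top_n)
    k3 = select_kmer_vocabulary(positives, 3, top_n)
    total: Counter = Counter()
    for rec in positives:
        total.update(kmer_counts(rec.sequence, 2))
        total.update(kmer_counts(rec.sequence, 3))
    counts = {m: total[m] for m in k2 + k3}
    return KmerVocabulary(k2=k2, k3=k3, provenance=provenance, counts=counts)


def kmer_fractions(sequence: str, vocabulary: Sequence[str]) -> np.ndarray:
    """Occurrence fraction of each vocabulary k-mer: count / (L - k + 1).

    Counting is overlapping; sequences shorter than k give zeros.
    """
    if not vocabulary:
        raise ValueError("empty vocabulary")
    ks = {len(m) for m in vocabulary}
    counters = {k: kmer_counts(sequence, k) for k in ks}
    windows = {k: max(len(sequence) - k + 1, 0) for k in ks}
    out = np.zeros(len(vocabulary))
    for i, m in enumerate(vocabulary):
        k = len(m)
        if windows[k]:
            out[i] = counters[k][m] / windows[k]
    return out


# ---------------------------------------------------------------------------
# feature table assembly
# ---------------------------------------------------------------------------

def build_base_feature_table(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Vocabulary-independent block: 19 physchem + 20 composition columns."""
    rows = []
    for rec in records:
        row = compute_physchem(rec)
        row.update(composition_fractions(rec.sequence))
        rows.append(row)
    return pd.DataFrame(rows, index=[r.accession for r in records])


def build_kmer_feature_table(
    records: Sequence[ProteinRecord], vocabulary: KmerVocabulary
) -> pd.DataFrame:
    vocab = vocabulary.k2 + vocabulary.k3
    data = np.vstack([kmer_fractions(r.sequence, vocab) for r in records])
    return pd.DataFrame(
        data, index=[r.accession for r in records], columns=vocabulary.columns
    )


def build_feature_table(
    records: Sequence[ProteinRecord],
    vocabulary: KmerVocabulary,
    base: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full proteins x 139 feature matrix (physchem + composition + k-mer).

    *base* optionally supplies a precomputed vocabulary-independent block
    (used to avoid recomputation across CV folds). The vocabulary must
    come from training positives only; pass the same object used at fit
    time when featurizing prediction targets.
    """
    accs = [r.accession for r in records]
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate accessions in records")
    if base is None:
        base = build_base_feature_table(records)
    else:
        base = base.loc[accs]
    table = pd.concat([base, build_kmer_feature_table(records, vocabulary)], axis=1)
    if not np.isfinite(table.to_numpy()).all():
        bad = table.columns[~np.isfinite(table.to_numpy()).all(axis=0)]
        raise ValueError(f"non-finite feature values in columns {list(bad)}")
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="accession")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")
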