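"""Random-forest granule classifiers: cross-validation, training,
proteome-wide prediction, tier identification rates, and the
group-comparison statistics used to characterize granule proteins.

The classifier is a standard random forest over the 139-column sequence
feature representation. Cross-validation is stratified 10-fold; in the
default strict mode the k-mer vocabulary is re-selected from each
training fold's positives so that vocabulary selection never sees
held-out proteins.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .seqfeat import (
    KmerVocabulary,
    ProteinRecord,
    build_base_feature_table,
    build_feature_table,
    select_vocabulary,
)

DEFAULT_N_ESTIMATORS = 500
HIGH_CONFIDENCE_P = 0.7


@dataclass
class CVResult:
    """Per-fold metrics and averaged Gini importances of a 10-fold CV."""

    fold_auc: np.ndarray
    fold_pr_auc: np.ndarray
    importances: pd.Series  # mean across folds, indexed by feature name
    fold_assignment: dict[str, int]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.fold_auc)

    @property
    def mean_auc(self) -> float:
        return float(self.fold_auc.mean())

    @property
    def sem_auc(self) -> float:
        return float(self.fold_auc.std(ddof=1) / np.sqrt(self.n_folds))

    @property
    def mean_pr_auc(self) -> float:
        return float(self.fold_pr_auc.mean())

    @property
    def sem_pr_auc(self) -> float:
        return float(self.fold_pr_auc.std(ddof=1) / np.sqrt(self.n_folds))

    def summary(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "mean_auc": self.mean_auc,
            "sem_auc": self.sem_auc,
            "mean_pr_auc": self.mean_pr_auc,
            "sem_pr_auc": self.sem_pr_auc,
            "seed": self.seed,
        }


def _make_forest(seed: int, n_estimators: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def cross_validate(
    records: Sequence[ProteinRecord],
    labels: Sequence[int],
    seed: int = 0,
    n_folds: int = 10,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    vocab_mode: str = "strict",
    vocabulary: KmerVocabulary | None = None,
    top_n_kmers: int = 50,
) -> CVResult:
    """Stratified k-fold CV with per-fold AUC, PR-AUC and importances.

    ``vocab_mode='strict'`` (default) re-selects the k-mer vocabulary
    from each training fold's positives, avoiding selection leakage;
    ``'fast'`` uses the supplied *vocabulary* for every fold. Per-fold
    Gini importances are averaged by feature name over the union of
    columns (a k-mer absent from a fold's vocabulary contributes 0 for
    that fold), which preserves the unit sum.
    """
    labels = np.asarray(labels, dtype=int)
    if len(records) != len(labels):
        raise ValueError("records and labels length mismatch")
    if len(records) < 20:
        raise ValueError("need at least 20 samples for cross-validation")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must be binary 0/1 with both classes present")
    if vocab_mode not in ("strict", "fast"):
        raise ValueError(f"unknown vocab_mode {vocab_mode!r}")
    if vocab_mode == "fast" and vocabulary is None:
        raise ValueError("fast mode requires a vocabulary")

    base = build_base_feature_table(records)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_auc, fold_pr = [], []
    importance_sum: dict[str, float] = {}
    fold_assignment: dict[str, int] = {}
    for fold, (train_idx, test_idx) in enumerate(splitter.split(base, labels)):
        train_recs = [records[i] for i in train_idx]
        test_recs = [records[i] for i in test_idx]
        if len(set(labels[test_idx])) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        if vocab_mode == "strict":
            fold_positives = [r for r, y in zip(train_recs, labels[train_idx]) if y == 1]
            vocab = select_vocabulary(
                fold_positives, top_n=top_n_kmers, provenance=f"fold{fold}"
            )
        else:
            vocab = vocabulary
        X_train = build_feature_table(train_recs, vocab, base=base)
        X_test = build_feature_table(test_recs, vocab, base=base)
        forest = _make_forest(seed, n_estimators)
        forest.fit(X_train, labels[train_idx])
        p = forest.predict_proba(X_test)[:, 1]
        fold_auc.append(roc_auc_score(labels[test_idx], p))
        fold_pr.append(average_precision_score(labels[test_idx], p))
        for name, imp in zip(X_train.columns, forest.feature_importances_):
            importance_sum[name] = importance_sum.get(name, 0.0) + imp
        for rec in test_recs:
            fold_assignment[rec.accession] = fold
    importances = pd.Series(importance_sum).sort_values(ascending=False) / n_folds
    return CVResult(
        fold_auc=np.array(fold_auc),
        fold_pr_auc=np.array(fold_pr),
        importances=importances,
        fold_assignment=fold_assignment,
        seed=seed,
    )


@dataclass
class TrainedModel:
    """Fitted forest plus the exact feature schema it was trained with."""

    forest: RandomForestClassifier
    columns: list[str]
    vocabulary: KmerVocabulary
    fingerprint: str
    seed: int

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} is not a TrainedModel bundle")
        return model

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Positive-class vote fraction per row, after schema check."""
        missing = [c for c in self.columns if c not in features.columns]
        extra = [c for c in features.columns if c not in self.columns]
        if missing or extra:
            raise ValueError(
                f"feature columns mismatch: missing={missing[:5]}, extra={extra[:5]}"
            )
        if features.index.duplicated().any():
            dups = features.index[features.index.duplicated()].tolist()
            raise ValueError(f"duplicate accession rows: {dups[:5]}")
        p = self.forest.predict_proba(features[self.columns])[:, 1]
        return pd.Series(p, index=features.index, name="p")


def _fingerprint(accessions: Sequence[str], labels: np.ndarray) -> str:
    digest = hashlib.sha256()
    for acc, y in zip(accessions, labels):
        digest.update(f"{acc}:{int(y)};".encode())
    return digest.hexdigest()[:16]


def train_full(
    features: pd.DataFrame,
    labels: Sequence[int],
    vocabulary: KmerVocabulary,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> TrainedModel:
    """Fit a forest on the full learning set and bundle its schema."""
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(features.to_numpy()).all():
        raise ValueError("non-finite feature values")
    forest = _make_forest(seed, n_estimators)
    forest.fit(features, labels)
    return TrainedModel(
        forest=forest,
        columns=list(features.columns),
        vocabulary=vocabulary,
        fingerprint=_fingerprint(list(features.index), labels),
        seed=seed,
    )


def predict_proteome(
    model: TrainedModel,
    features: pd.DataFrame,
    high_confidence_p: float = HIGH_CONFIDENCE_P,
) -> pd.DataFrame:
    """Granule propensity table, sorted by descending probability.

    The high-confidence flag marks p > *high_confidence_p* (default 0.7,
    the cutoff used to define the high-confidence predicted proteome).
    """
    p = model.predict(features)
    table = pd.DataFrame(
        {"p": p, "high_confidence": p > high_confidence_p}, index=features.index
    )
    return table.sort_values("p", ascending=False, kind="mergesort")


def tier_identification_rates(
    model: TrainedModel,
    features_by_tier: Mapping[int, pd.DataFrame],
    threshold: float = 0.5,
) -> dict[int, float]:
    """Percent of catalogue proteins called granule-positive, per tier.

    rate(t) = 100 x fraction of tier-t proteins with p >= threshold.
    Identification rates should decay with tier because tier encodes
    evidence confidence (tier 1 strongest).
    """
    if not features_by_tier:
        raise ValueError("empty tier map")
    rates: dict[int, float] = {}
    for tier in (1, 2, 3, 4):
        if tier not in features_by_tier or len(features_by_tier[tier]) == 0:
            warnings.warn(f"tier {tier} missing or empty; skipped")
            continue
        p = model.predict(features_by_tier[tier])
        rates[tier] = float((p >= threshold).mean() * 100.0)
    return rates


# ---------------------------------------------------------------------------
# group-comparison statistics
# ---------------------------------------------------------------------------

def compare_feature_distributions(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    feature_names: Sequence[str],
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per feature with BH adjustment.

    Direction is reported as the median difference (a - b). A feature
    constant and equal in both groups is flagged with p = 1.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    for name in feature_names:
        if name not in group_a.columns or name not in group_b.columns:
            raise KeyError(f"unknown feature column {name!r}")
        a = group_a[name].to_numpy()
        b = group_b[name].to_numpy()
        constant = a.std() == 0 and b.std() == 0 and a[0] == b[0]
        if constant:
            u, p = np.nan, 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "feature": name,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "median_diff": float(np.median(a) - np.median(b)),
                "u_stat": u,
                "p_raw": float(p),
                "constant": constant,
            }
        )
    report = pd.DataFrame(rows)
    report["p_adj"] = multipletests(report["p_raw"], method="fdr_bh")[1]
    report["direction"] = np.sign(report["median_diff"]).astype(int)
    return report


MOTIF_PANEL = ("RG", "RGG", "GRG")


def kmer_enrichment_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    kmers: Sequence[str],
) -> pd.DataFrame:
    """Mann-Whitney enrichment of k-mer fraction columns (a vs b).

    *kmers* may be raw k-mers ("RG") or prefixed column names ("k2_RG").
    The RG/RGG/GRG entries are flagged as the RGG/RG-motif panel.
    """
    columns = []
    for m in kmers:
        col = m if m.startswith(("k2_", "k3_")) else f"k{len(m)}_{m}"
        if col not in group_a.columns:
            raise KeyError(f"unknown k-mer column {col!r}")
        columns.append(col)
    report = compare_feature_distributions(group_a, group_b, columns)
    report["kmer"] = [c.split("_", 1)[1] for c in report["feature"]]
    report["motif_panel"] = report["kmer"].isin(MOTIF_PANEL)
    return report


def auc_pairwise_concordance(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AUC as the positive/negative pairwise concordance rate (ties = 1/2).

    Exposed for small-sample checks against the trapezoidal ROC AUC.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))
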