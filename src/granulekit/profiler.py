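"""Per-position granule-propensity profiles along single proteins.

A trained classifier is slid along the sequence in fixed-length windows;
each window subsequence is featurized exactly like a full protein and
scored, giving a per-window probability track together with windowed
GRAVY and cysteine-fraction tracks. Probability peaks localize
granule-prone regions (disordered, hydrophilic, cysteine-poor stretches
such as RGG-rich IDRs or RNA-binding domains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .granulerf import TrainedModel
from .seqfeat import ProteinRecord, build_feature_table, compute_gravy


@dataclass
class Peak:
    start: int  # 0-based inclusive
    end: int  # exclusive
    max_p: float
    mean_gravy: float
    mean_cys_fraction: float


@dataclass
class WindowProfile:
    accession: str
    window_length: int
    step: int
    windows: pd.DataFrame  # columns: start, end, p, gravy, cys_fraction
    per_residue_p: np.ndarray

    @property
    def length(self) -> int:
        return len(self.per_residue_p)


def _window_spans(L: int, window: int, step: int) -> list[tuple[int, int]]:
    """Half-open [start, end) spans; terminal stub kept when >= window/2."""
    if L < window / 2:
        warnings.warn(
            f"sequence length {L} < window/2 ({window / 2:.0f}); "
            "using a single whole-sequence window"
        )
        return [(0, L)]
    spans = []
    start = 0
    while start + window <= L:
        spans.append((start, start + window))
        start += step
    covered = spans[-1][1] if spans else 0
    if covered < L:
        tail_start = start if spans else 0
        if L - tail_start >= window / 2:
            spans.append((tail_start, L))
    return spans


def sliding_window_propensity(
    model: TrainedModel,
    record: ProteinRecord,
    window: int = 50,
    step: int = 5,
) -> WindowProfile:
    """Score sliding windows of one protein with a trained model.

    Each window subsequence is featurized as if it were a full protein
    (so the length feature equals the window length) using the model's
    own k-mer vocabulary. The per-residue track is the mean of all
    covering window scores; residues past the last window inherit the
    final window's score so the track always has length L.
    """
    if window < 10:
        raise ValueError("window must be >= 10")
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = record.sequence
    spans = _window_spans(len(seq), window, step)
    sub_records = [
        ProteinRecord(f"{record.accession}|{s}-{e}", seq[s:e]) for s, e in spans
    ]
    features = build_feature_table(sub_records, model.vocabulary)
    p = model.predict(features).to_numpy()
    gravy = np.array([compute_gravy(seq[s:e]) for s, e in spans])
    cys = np.array([seq[s:e].count("C") / (e - s) for s, e in spans])
    windows = pd.DataFrame(
        {
            "start": [s for s, _ in spans],
            "end": [e for _, e in spans],
            "p": p,
            "gravy": gravy,
            "cys_fraction": cys,
        }
    )
    L = len(seq)
    total = np.zeros(L)
    cover = np.zeros(L)
    for (s, e), score in zip(spans, p):
        total[s:e] += score
        cover[s:e] += 1
    uncovered = cover == 0
    track = np.divide(total, cover, out=np.zeros(L), where=~uncovered)
    if uncovered.any():
        track[uncovered] = p[-1]
    return WindowProfile(
        accession=record.accession,
        window_length=window,
        step=step,
        windows=windows,
        per_residue_p=track,
    )


def call_peaks(
    profile: WindowProfile, min_p: float = 0.7, min_len: int = 10
) -> list[Peak]:
    """Maximal runs of per-residue probability >= min_p, length >= min_len.

    Each peak is annotated with the mean windowed GRAVY and cysteine
    fraction over the windows overlapping its span.
    """
    track = profile.per_residue_p
    peaks: list[Peak] = []
    start = None
    for i, value in enumerate(np.append(track >= min_p, False)):
        if value and start is None:
            start = i
        elif not value and start is not None:
            if i - start >= min_len:
                peaks.append(_annotate_peak(profile, start, i))
            start = None
    return peaks


def _annotate_peak(profile: WindowProfile, start: int, end: int) -> Peak:
    w = profile.windows
    overlap = (w["start"] < end) & (w["end"] > start)
    sel = w.loc[overlap]
    return Peak(
        start=start,
        end=end,
        max_p=float(profile.per_residue_p[start:end].max()),
        mean_gravy=float(sel["gravy"].mean()),
        mean_cys_fraction=float(sel["cys_fraction"].mean()),
    )


def write_profile_tsv(profile: WindowProfile, path: str | Path) -> None:
    profile.windows.to_csv(path, sep="\t", index=False)


def write_peaks_bed(profile: WindowProfile, peaks: list[Peak], path: str | Path) -> None:
    """Peaks as BED (0-based half-open); score = max p scaled to 0-1000."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks, 1):
            score = int(round(min(max(pk.max_p, 0.0), 1.0) * 1000))
            fh.write(
                f"{profile.accession}\t{pk.start}\t{pk.end}\tpeak{i}\t{score}\t.\n"
            )
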