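"""AHA-style segmental partition and per-subject diagnostic performance.

Each short-axis slice is divided into equal angular sectors (6 for basal/mid
slices, 4 for apical) counter-clockwise from the anterior RV insertion
reference angle.  A segment is called positive for hemorrhage when the
hypointense area exceeds 1% of the segment's cross-sectional area (strict
inequality).  Dark-blood calls are scored against bright-blood calls as the
ground truth: sensitivity, specificity, accuracy (TP+TN over all evaluated
segments) and AUC from the continuous per-segment hypointense fraction via
the rank-sum (Mann-Whitney) formulation with midrank ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .phantom import pixel_polar

__all__ = [
    "AHAPartition",
    "Contingency",
    "DxSummary",
    "partition_slice",
    "partition_stack",
    "segment_measurements",
    "call_segments",
    "contingency",
    "auc_rank_sum",
    "dx_summary",
]


@dataclass
class AHAPartition:
    """Segment-id image (ids 1..n per myocardial pixel, 0 elsewhere)."""

    segment_labels: np.ndarray
    n_segments_per_slice: int
    ref_angle: float


@dataclass
class Contingency:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DxSummary:
    """Per-subject diagnostic summary; undefined quantities are NaN, never 0."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float


def partition_slice(
    myo_mask: np.ndarray,
    center: tuple[float, float],
    ref_angle: float,
    n_segments: int = 6,
) -> np.ndarray:
    """Assign each myocardial pixel of one slice to an equal angular sector.

    Sectors run counter-clockwise from ``ref_angle``; a pixel exactly on a
    sector boundary goes to the lower-indexed of the two adjacent segments.
    Returns an int array with segment ids 1..n (0 outside myocardium).
    """
    if n_segments not in (4, 6):
        raise ValueError("n_segments must be 4 (apical) or 6 (basal/mid)")
    myo_mask = np.asarray(myo_mask, dtype=bool)
    if not np.any(myo_mask):
        raise ValueError("empty myocardium mask")
    _, theta = pixel_polar(myo_mask.shape[-1], center)
    rel = (theta - ref_angle) % 360.0
    width = 360.0 / n_segments
    # boundary pixels (rel an exact multiple of width) belong to the segment
    # below the boundary; rel == 0 wraps to segment 0
    k = np.ceil(rel / width).astype(int) - 1
    k[rel == 0.0] = 0
    k = np.clip(k, 0, n_segments - 1)
    out = np.zeros(myo_mask.shape, dtype=np.int32)
    out[myo_mask] = k[myo_mask] + 1
    return out


def partition_stack(
    myo_mask: np.ndarray,
    center: tuple[float, float],
    ref_angle: float,
    n_segments: int = 6,
) -> AHAPartition:
    """Partition every slice of a myocardium stack."""
    labels = np.stack(
        [partition_slice(myo_mask[s], center, ref_angle, n_segments) for s in range(myo_mask.shape[0])]
    )
    return AHAPartition(segment_labels=labels, n_segments_per_slice=n_segments, ref_angle=ref_angle)


def segment_measurements(hypo_mask: np.ndarray, partition: AHAPartition) -> pd.DataFrame:
    """Per-(slice, segment) myocardial and hypointense areas and fraction."""
    hypo_mask = np.asarray(hypo_mask, dtype=bool)
    labels = partition.segment_labels
    if hypo_mask.shape != labels.shape:
        raise ValueError("masks must be slice-matched")
    rows = []
    for s in range(labels.shape[0]):
        for seg in range(1, partition.n_segments_per_slice + 1):
            in_seg = labels[s] == seg
            myo_area = int(in_seg.sum())
            hypo_area = int((in_seg & hypo_mask[s]).sum())
            rows.append(
                dict(
                    slice=s,
                    segment_id=seg,
                    myo_area_px=myo_area,
                    hypo_area_px=hypo_area,
                    hypo_fraction=hypo_area / myo_area if myo_area else np.nan,
                )
            )
    return pd.DataFrame(rows)


def call_segments(
    measurements: pd.DataFrame,
    positivity_threshold: float = 0.01,
    exclusions: set[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Positive iff hypo_fraction > threshold (strict, per "exceeded").

    ``exclusions`` is a set of (slice, segment_id) pairs (e.g. off-resonance
    affected inferolateral segments); excluded segments carry the flag and are
    dropped from all downstream counts.
    """
    if not 0.0 < positivity_threshold < 1.0:
        raise ValueError("positivity_threshold must be in (0, 1)")
    exclusions = exclusions or set()
    out = measurements.copy()
    out["positive"] = out["hypo_fraction"] > positivity_threshold
    out["excluded"] = [
        (s, g) in exclusions for s, g in zip(out["slice"], out["segment_id"])
    ]
    return out


def contingency(calls_test: pd.DataFrame, calls_ref: pd.DataFrame) -> Contingency:
    """2x2 cross-tabulation of test calls against reference calls.

    Excluded segments (in either arm) are dropped; the remaining segment index
    sets must match.
    """
    key = ["slice", "segment_id"]
    t = calls_test.loc[~calls_test["excluded"]].set_index(key)["positive"]
    r = calls_ref.loc[~calls_ref["excluded"]].set_index(key)["positive"]
    if not t.index.equals(r.index):
        raise ValueError("segment sets differ between test and reference arms")
    t_arr, r_arr = t.to_numpy(bool), r.to_numpy(bool)
    return Contingency(
        tp=int((t_arr & r_arr).sum()),
        fp=int((t_arr & ~r_arr).sum()),
        tn=int((~t_arr & ~r_arr).sum()),
        fn=int((~t_arr & r_arr).sum()),
    )


def auc_rank_sum(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank-sum (Mann-Whitney) identity with midrank ties.

    ``scores`` are continuous test scores, ``labels`` the binary reference.
    NaN when either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # midranks
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def dx_summary(
    cont: Contingency, test_fractions: np.ndarray, ref_calls: np.ndarray
) -> DxSummary:
    """Sensitivity, specificity, accuracy and rank-sum AUC for one subject."""
    if cont.total == 0:
        raise ValueError("no segments evaluated")
    sens = cont.tp / (cont.tp + cont.fn) if (cont.tp + cont.fn) > 0 else float("nan")
    spec = cont.tn / (cont.tn + cont.fp) if (cont.tn + cont.fp) > 0 else float("nan")
    acc = (cont.tp + cont.tn) / cont.total
    auc = auc_rank_sum(np.asarray(test_fractions), np.asarray(ref_calls))
    return DxSummary(sensitivity=sens, specificity=spec, accuracy=acc, auc=auc)
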