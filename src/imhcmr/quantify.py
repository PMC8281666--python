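"""Threshold-based infarct and hemorrhage quantification.

Remote myocardium serves as the reference region: the infarct (MI) zone is
myocardium with LGE signal at least 5 reference-SDs above the reference mean,
and the hemorrhage (IMH) core is the set of pixels within the MI zone whose
T2*-weighted signal is at least 2 reference-SDs below the reference mean,
cleaned of sub-threshold speckle by discarding 4-connected components smaller
than ``min_core_pixels``.  IMH extent is the hemorrhage volume as a percent of
the imaged LV myocardial volume.

Notes on conventions: region SDs use the population (n) divisor; the
"at least k SD" comparisons are inclusive, except that a zero reference SD
(noise-free degenerate case) falls back to a strict comparison — with zero
spread the inclusive rule would flag the reference region itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import SimulatedImage, pixel_polar, _ang_dist

__all__ = [
    "RegionStats",
    "ROISpec",
    "SegmentationResult",
    "region_stats",
    "air_roi_mask",
    "select_remote_roi",
    "detect_mi_zone",
    "detect_imh",
    "imh_extent",
    "segment_subject",
]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class RegionStats:
    """Mean/SD/count of signal over a region of interest."""

    mean_si: float
    sd_si: float
    n_pixels: int


@dataclass
class ROISpec:
    """A binary region-of-interest mask (same shape as the image stack)."""

    mask: np.ndarray


@dataclass
class SegmentationResult:
    """Per-subject-arm segmentation output."""

    mi_mask: np.ndarray
    imh_mask: np.ndarray
    mi_threshold: float
    imh_threshold: float
    remote_stats: RegionStats
    imh_extent_pct: float
    degenerate: bool = False


def _as_array(image) -> np.ndarray:
    return image.intensity if isinstance(image, SimulatedImage) else np.asarray(image)


def region_stats(image, mask: np.ndarray) -> RegionStats:
    """Mean and population SD over the masked pixels."""
    arr = _as_array(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {arr.shape}")
    vals = arr[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    return RegionStats(mean_si=float(vals.mean()), sd_si=float(vals.std()), n_pixels=int(vals.size))


def air_roi_mask(shape: tuple[int, ...], size: int = 40) -> np.ndarray:
    """Corner background-air ROI (top-left ``size`` x ``size`` of every slice)."""
    size = min(size, shape[-1] // 4)
    mask = np.zeros(shape, dtype=bool)
    mask[..., :size, :size] = True
    return mask


def select_remote_roi(
    lge,
    myo_mask: np.ndarray,
    mi_mask: np.ndarray,
    jitter_seed: int | None = None,
    ref_angle: float = 0.0,
    width_deg: float = 60.0,
    rotation_jitter_deg: float = 20.0,
    width_jitter_deg: float = 10.0,
) -> ROISpec:
    """Reference ROI: a myocardial sector diametrically opposite the infarct.

    The infarct center angle is estimated from the MI mask (circular mean of
    pixel angles about the myocardial centroid); with no infarct the ROI is
    centered at ``ref_angle`` + 180 deg.  ``jitter_seed`` rotates and resizes
    the sector within bounds, emulating reader-to-reader ROI placement.  The
    returned ROI always excludes the MI mask (remote myocardium is the region
    absent of hyperintensity on LGE).
    """
    arr = _as_array(lge)
    myo_mask = np.asarray(myo_mask, dtype=bool)
    mi_mask = np.asarray(mi_mask, dtype=bool)
    if not np.any(myo_mask & ~mi_mask):
        raise ValueError("infarct covers the entire myocardium; no remote region")

    rows, cols = np.nonzero(myo_mask.any(axis=0))
    center = (float(rows.mean()), float(cols.mean()))
    n = myo_mask.shape[-1]
    _, theta = pixel_polar(n, center)

    mi_any = mi_mask.any(axis=0)
    if np.any(mi_any):
        ang = np.radians(theta[mi_any])
        mi_angle = np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0
    else:
        mi_angle = ref_angle % 360.0

    rot, dw = 0.0, 0.0
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        rot = rng.uniform(-rotation_jitter_deg, rotation_jitter_deg)
        dw = rng.uniform(-width_jitter_deg, width_jitter_deg)
    roi_center = (mi_angle + 180.0 + rot) % 360.0
    width = max(width_deg + dw, 10.0)

    for _ in range(20):
        sector = _ang_dist(theta, roi_center) <= width / 2.0
        roi = myo_mask & sector[None, ...] & ~mi_mask
        if np.any(roi):
            return ROISpec(mask=roi)
        width *= 1.5  # widen until some remote myocardium is covered
    raise ValueError("could not place a remote ROI disjoint from the infarct")


def detect_mi_zone(lge, myo_mask: np.ndarray, remote: ROISpec, k: float = 5.0):
    """Infarct zone: myocardial pixels >= remote mean + k * remote SD on LGE.

    Returns ``(mask, threshold, degenerate)``; ``degenerate`` marks a zero
    remote SD (strict comparison used).
    """
    arr = _as_array(lge)
    myo_mask = np.asarray(myo_mask, dtype=bool)
    stats = region_stats(arr, remote.mask)
    thr = stats.mean_si + k * stats.sd_si
    degenerate = stats.sd_si == 0.0
    mask = (arr > thr) if degenerate else (arr >= thr)
    return mask & myo_mask, float(thr), degenerate


def detect_imh(
    t2sw,
    mi_mask: np.ndarray,
    remote: ROISpec,
    min_core_pixels: int = 2,
    k: float = 2.0,
):
    """Hemorrhage core: MI pixels <= remote mean - k * remote SD on T2*w.

    Per-slice 4-connected components smaller than ``min_core_pixels`` are
    discarded as noise speckle.  Pixel-level thresholding guarantees that
    every retained core's mean also satisfies the k-SD criterion.  Returns
    ``(mask, threshold, degenerate)``.
    """
    arr = _as_array(t2sw)
    mi_mask = np.asarray(mi_mask, dtype=bool)
    stats = region_stats(arr, remote.mask)
    thr = stats.mean_si - k * stats.sd_si
    degenerate = stats.sd_si == 0.0
    raw = ((arr < thr) if degenerate else (arr <= thr)) & mi_mask
    if min_core_pixels > 1:
        cleaned = np.zeros_like(raw)
        for s in range(raw.shape[0]):
            lab, n = ndimage.label(raw[s], structure=FOUR_CONNECTED)
            if n == 0:
                continue
            sizes = np.bincount(lab.ravel())
            keep = np.flatnonzero(sizes >= min_core_pixels)
            keep = keep[keep > 0]
            cleaned[s] = np.isin(lab, keep)
        raw = cleaned
    return raw, float(thr), degenerate


def imh_extent(imh_mask: np.ndarray, lv_myo_mask: np.ndarray) -> float:
    """IMH volume as a percent of the imaged LV myocardial volume.

    Voxel size is uniform and slice-matched, so it cancels.
    """
    imh_mask = np.asarray(imh_mask, dtype=bool)
    lv_myo_mask = np.asarray(lv_myo_mask, dtype=bool)
    if imh_mask.shape != lv_myo_mask.shape:
        raise ValueError("masks must be slice-matched")
    n_myo = int(lv_myo_mask.sum())
    if n_myo == 0:
        raise ValueError("empty myocardium mask")
    return 100.0 * float(imh_mask.sum()) / n_myo


def segment_subject(
    lge,
    t2sw,
    myo_mask: np.ndarray,
    jitter_seed: int | None = None,
    mi_k: float = 5.0,
    imh_k: float = 2.0,
    min_core_pixels: int = 2,
    roi_kwargs: dict | None = None,
) -> SegmentationResult:
    """Full quantification chain for one arm of one subject.

    A provisional MI mask from a robust (median/MAD) LGE threshold anchors the
    remote-ROI placement; the final MI zone and IMH core use the
    reader-jittered ROI.
    """
    roi_kwargs = roi_kwargs or {}
    lge_arr = _as_array(lge)
    myo = np.asarray(myo_mask, dtype=bool)
    vals = lge_arr[myo]
    med = np.median(vals)
    mad = 1.4826 * np.median(np.abs(vals - med))  # robust SD; MI is the minority class
    mi0 = (lge_arr > med + mi_k * mad) & myo
    roi = select_remote_roi(lge, myo_mask, mi0, jitter_seed=jitter_seed, **roi_kwargs)
    mi_mask, mi_thr, deg_mi = detect_mi_zone(lge, myo_mask, roi, k=mi_k)
    remote_t2 = region_stats(t2sw, roi.mask)
    imh_mask, imh_thr, deg_imh = detect_imh(
        t2sw, mi_mask, roi, min_core_pixels=min_core_pixels, k=imh_k
    )
    return SegmentationResult(
        mi_mask=mi_mask,
        imh_mask=imh_mask,
        mi_threshold=mi_thr,
        imh_threshold=imh_thr,
        remote_stats=remote_t2,
        imh_extent_pct=imh_extent(imh_mask, myo_mask),
        degenerate=deg_mi or deg_imh,
    )
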