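"""ROI statistics and threshold segmentation (5-SD infarct, 2-SD hemorrhage)."""

from __future__ import annotations

import numpy as np
import pytest

import imhcmr as m
from imhcmr.phantom import pixel_polar
from imhcmr.presets import TissueClass


def _img(values):
    """Wrap a flat value list into a (1, 1, n) stack."""
    arr = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return arr


# ---------------------------------------------------------------------------
# region statistics


def test_region_stats_population_sd():
    arr = _img([4.0, 6.0, 99.0])
    mask = np.array([[[True, True, False]]])
    st = m.region_stats(arr, mask)
    assert st.mean_si == 5.0
    assert st.sd_si == 1.0  # population (n) divisor
    assert st.n_pixels == 2


def test_region_stats_constant_region():
    st = m.region_stats(_img([7.0, 7.0, 7.0]), np.ones((1, 1, 3), bool))
    assert st.mean_si == 7.0 and st.sd_si == 0.0


def test_region_stats_contract_errors():
    arr = _img([1.0, 2.0])
    with pytest.raises(ValueError, match="shape"):
        m.region_stats(arr, np.ones((1, 1, 3), bool))
    with pytest.raises(ValueError, match="empty"):
        m.region_stats(arr, np.zeros((1, 1, 2), bool))


# ---------------------------------------------------------------------------
# threshold rules, hand-evaluated


def test_mi_rule_hand_case():
    """Remote mean 50, SD 4 -> threshold 70; 'at least' means inclusive."""
    vals = [46.0, 54.0, 60.0, 70.0, 95.0]
    arr = _img(vals)
    remote = m.ROISpec(mask=np.array([[[1, 1, 0, 0, 0]]], dtype=bool))
    myo = np.array([[[0, 0, 1, 1, 1]]], dtype=bool)
    mask, thr, degenerate = m.detect_mi_zone(arr, myo, remote)
    assert thr == 70.0 and not degenerate
    assert mask.tolist() == [[[False, False, False, True, True]]]


def test_imh_rule_hand_case():
    """Remote mean 100, SD 5 -> threshold 90, inclusive."""
    arr = _img([95.0, 105.0, 95.0, 88.0, 70.0, 92.0])
    remote = m.ROISpec(mask=np.array([[[1, 1, 0, 0, 0, 0]]], dtype=bool))
    mi = np.array([[[0, 0, 1, 1, 1, 1]]], dtype=bool)
    mask, thr, _ = m.detect_imh(arr, mi, remote, min_core_pixels=1)
    assert thr == 90.0
    assert mask.tolist() == [[[False, False, False, True, True, False]]]


def test_imh_small_cores_discarded():
    arr = np.full((1, 5, 5), 100.0)
    arr[0, 1, 1] = 10.0  # isolated single pixel
    arr[0, 3, 1:3] = 10.0  # 4-connected pair
    remote = m.ROISpec(mask=np.zeros((1, 5, 5), bool))
    remote.mask[0, 0, 3:] = True
    arr[0, 0, 3] = 98.0
    arr[0, 0, 4] = 102.0
    mi = np.ones((1, 5, 5), bool)
    mask, _, _ = m.detect_imh(arr, mi, remote, min_core_pixels=2)
    assert not mask[0, 1, 1]
    assert mask[0, 3, 1] and mask[0, 3, 2]


def test_imh_rule_affine_invariance(noisy_subject):
    """Jointly rescaling image and reference leaves the detected core unchanged."""
    sim = noisy_subject
    myo = sim["label_map"].myocardium_mask
    seg = m.segment_subject(sim["lge"], sim["bright"], myo)
    roi = m.select_remote_roi(sim["lge"], myo, seg.mi_mask)
    mask1, _, _ = m.detect_imh(sim["bright"], seg.mi_mask, roi)
    scaled = m.SimulatedImage(intensity=3.5 * sim["bright"].intensity + 11.0)
    mask2, _, _ = m.detect_imh(scaled, seg.mi_mask, roi)
    assert np.array_equal(mask1, mask2)


# ---------------------------------------------------------------------------
# extent


def test_extent_hand_cases():
    myo = np.zeros((2, 40, 40), bool)
    myo[:, :25, :20] = True  # 1000 voxels
    imh = np.zeros_like(myo)
    assert m.imh_extent(imh, myo) == 0.0
    imh[0, :5, :10] = True  # 50 voxels
    assert m.imh_extent(imh, myo) == pytest.approx(5.0)
    assert m.imh_extent(myo, myo) == 100.0
    with pytest.raises(ValueError):
        m.imh_extent(imh, np.zeros_like(myo))
    with pytest.raises(ValueError):
        m.imh_extent(imh[:1], myo)


# ---------------------------------------------------------------------------
# remote ROI placement


def test_remote_roi_opposite_reference_when_no_mi(noise_free_subject):
    lm = noise_free_subject["label_map"]
    myo = lm.myocardium_mask
    empty_mi = np.zeros_like(myo)
    roi = m.select_remote_roi(noise_free_subject["lge"], myo, empty_mi, ref_angle=30.0)
    _, theta = pixel_polar(lm.geometry.grid_size, lm.geometry.center)
    ang = np.radians(theta[roi.mask.any(axis=0)])
    mean_ang = np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0
    assert abs((mean_ang - 210.0 + 180.0) % 360.0 - 180.0) < 3.0


def test_remote_roi_deterministic_and_disjoint_from_mi(noisy_subject):
    sim = noisy_subject
    myo = sim["label_map"].myocardium_mask
    seg = m.segment_subject(sim["lge"], sim["bright"], myo)
    a = m.select_remote_roi(sim["lge"], myo, seg.mi_mask, jitter_seed=42)
    b = m.select_remote_roi(sim["lge"], myo, seg.mi_mask, jitter_seed=42)
    assert np.array_equal(a.mask, b.mask)
    for seed in range(100):
        roi = m.select_remote_roi(sim["lge"], myo, seg.mi_mask, jitter_seed=seed)
        assert not (roi.mask & seg.mi_mask).any()
        assert roi.mask.sum() > 0


def test_remote_roi_rejects_fully_infarcted_myocardium(noise_free_subject):
    myo = noise_free_subject["label_map"].myocardium_mask
    with pytest.raises(ValueError, match="entire myocardium"):
        m.select_remote_roi(noise_free_subject["lge"], myo, myo.copy())


# ---------------------------------------------------------------------------
# zero-noise end-to-end recovery


def test_noise_free_recovery_exact(noise_free_subject):
    sim = noise_free_subject
    truth = sim["truth"]
    myo = sim["label_map"].myocardium_mask
    true_mi_zone = truth.masks[TissueClass.MI] | truth.masks[TissueClass.IMH]
    for arm in ("bright", "dark"):
        seg = m.segment_subject(sim["lge"], sim[arm], myo)
        assert seg.degenerate  # zero remote SD flagged
        assert np.array_equal(seg.mi_mask, true_mi_zone)
        assert np.array_equal(seg.imh_mask, truth.masks[TissueClass.IMH])
        assert seg.imh_extent_pct == pytest.approx(truth.true_imh_extent)


def test_no_contrast_gives_empty_masks(small_geometry):
    """MI enhancement equal to remote yields an empty infarct on average."""
    lm = m.build_label_map(small_geometry)
    lge = m.render_lge(lm, {"mu_mi": 50.0, "mu_remote": 50.0, "noise_sigma": 0.0}, seed=0)
    myo = lm.myocardium_mask
    roi = m.select_remote_roi(lge, myo, np.zeros_like(myo))
    mask, _, degenerate = m.detect_mi_zone(lge, myo, roi)
    assert degenerate and not mask.any()
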