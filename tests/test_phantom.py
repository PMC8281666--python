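"""Phantom geometry, signal model and renderer."""

from __future__ import annotations

import math

import numpy as np
import pytest

import imhcmr as m
from imhcmr.phantom import dir_prep_factor
from imhcmr.presets import TissueClass


# ---------------------------------------------------------------------------
# label maps


def test_annulus_pixel_count_matches_analytic_area():
    geom = m.PhantomGeometry(grid_size=192, pixel_spacing=1.0, n_slices=1,
                             endo_radius=15.0, epi_radius=25.0)
    lm = m.build_label_map(geom)
    n_myo = int(lm.myocardium_mask.sum())
    analytic = math.pi * (25.0**2 - 15.0**2)  # 1256.6 mm^2 at 1 mm^2/px
    assert abs(n_myo - analytic) / analytic < 0.02


def test_zero_mi_span_gives_no_mi_and_no_imh():
    geom = m.PhantomGeometry(mi_angular_span=0.0, imh_angular_span=0.0)
    lm = m.build_label_map(geom)
    assert not lm.mask(TissueClass.MI).any()
    assert not lm.mask(TissueClass.IMH).any()


def test_full_circumference_transmural_mi_covers_all_myocardium():
    geom = m.PhantomGeometry(mi_angular_span=360.0, mi_transmurality=1.0,
                             imh_angular_span=0.0)
    lm = m.build_label_map(geom)
    assert lm.mask(TissueClass.MI).sum() == lm.myocardium_mask.sum()


def test_tissue_nesting_invariants():
    lm = m.build_label_map(m.PhantomGeometry())
    imh = lm.mask(TissueClass.IMH)
    mi = lm.mask(TissueClass.MI)
    myo = lm.myocardium_mask
    assert imh.sum() > 0 and mi.sum() > 0
    assert (imh & ~myo).sum() == 0  # IMH inside myocardium
    assert (mi & ~myo).sum() == 0
    stag = lm.mask(TissueClass.BLOOD_STAGNANT)
    # stagnant layer lies strictly inside the endocardial radius
    from imhcmr.phantom import pixel_polar

    r, _ = pixel_polar(lm.geometry.grid_size, lm.geometry.center)
    assert stag.sum() > 0
    assert np.all(r[stag.any(axis=0)] < lm.geometry.endo_radius)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(endo_radius=20.0, epi_radius=15.0),
        dict(mi_angular_span=-5.0),
        dict(imh_angular_span=120.0, mi_angular_span=100.0),
        dict(mi_transmurality=0.0),
        dict(imh_rim_floor=0.0),
        dict(stagnant_layer_thickness=-1.0),
    ],
)
def test_degenerate_geometry_rejected(kwargs):
    with pytest.raises(ValueError):
        m.PhantomGeometry(**kwargs)


# ---------------------------------------------------------------------------
# closed-form signal model


def test_bright_signal_limit_te_zero_long_rr():
    tis = m.Tissue(t1=1000.0, t2star=30.0, proton_density=80.0)
    seq = m.SequenceParams(prep="bright", te=0.0, rr=1e9, flip_angle=18.0)
    s = m.steady_state_signal(tis, seq)
    assert s == pytest.approx(80.0 * math.sin(math.radians(18.0)), rel=1e-9)


def test_perfect_dir_with_long_ti_equals_bright():
    tis = m.Tissue(t1=1000.0, t2star=30.0, proton_density=80.0)
    common = dict(te=14.5, rr=1e12, flip_angle=18.0)
    bright = m.SequenceParams(prep="bright", **common)
    dark = m.SequenceParams(prep="dark", ti=1e11, eta_nonsel=1.0, eta_sel=1.0,
                            kappa=1.0, **common)
    assert m.steady_state_signal(tis, dark) == pytest.approx(
        m.steady_state_signal(tis, bright), rel=1e-9
    )


def test_flowing_blood_nulls_at_t1_ln2():
    """Ideal single inversion of inflowing blood crosses zero at TI = T1 ln 2."""
    t1 = 1400.0
    ti_null = t1 * math.log(2.0)
    tis = m.Tissue(t1=t1, t2star=50.0, proton_density=100.0)
    mk = lambda ti: m.SequenceParams(prep="dark", te=14.5, rr=3000.0, flip_angle=18.0,
                                     ti=ti, eta_nonsel=1.0, eta_sel=1.0, kappa=1.0)
    assert m.steady_state_signal(tis, mk(ti_null), flowing=True) == pytest.approx(0.0, abs=1e-9)
    # strictly away from the null the signal is finite on both sides
    assert m.steady_state_signal(tis, mk(ti_null - 200), flowing=True) > 1e-3
    assert m.steady_state_signal(tis, mk(ti_null + 200), flowing=True) > 1e-3


def test_dark_bright_ratio_bounded_and_monotone():
    """f(TI) <= 1 on the whole (eta, kappa) grid; non-decreasing in eta and kappa."""
    t1 = 950.0
    etas = np.linspace(0.5, 0.999, 12)
    kappas = np.linspace(0.05, 1.0, 12)
    for ti in (300.0, 600.0, 820.0):
        grid = np.empty((len(etas), len(kappas)))
        for i, eta in enumerate(etas):
            for j, kap in enumerate(kappas):
                seq = m.SequenceParams(prep="dark", te=14.5, rr=857.0, flip_angle=18.0,
                                       ti=ti, eta_nonsel=eta, eta_sel=eta, kappa=kap)
                grid[i, j] = dir_prep_factor(t1, seq)
        assert np.all(grid <= 1.0 + 1e-12)
        assert np.all(np.diff(grid, axis=0) >= -1e-12)  # monotone in eta
        assert np.all(np.diff(grid, axis=1) >= -1e-12)  # monotone in kappa


def test_3t_preset_loses_more_signal_than_1p5t():
    ratios = {}
    for field in ("1.5T", "3T"):
        tis = m.tissue_preset(field, "acute")[TissueClass.REMOTE_MYO]
        bright = m.sequence_preset("bright", field)
        dark = m.sequence_preset("dark", field)
        ratios[field] = m.steady_state_signal(tis, dark) / m.steady_state_signal(tis, bright)
    assert ratios["3T"] < ratios["1.5T"] < 1.0


# ---------------------------------------------------------------------------
# rendering


def test_noise_free_render_is_piecewise_constant_signal_table(small_geometry):
    lm = m.build_label_map(small_geometry)  # uniform IMH core by default
    tissues = m.tissue_preset("1.5T", "acute")
    seq = m.sequence_preset("bright", "1.5T", noise_sigma=0.0)
    img = m.render_image(lm, tissues, seq, seed=0)
    from imhcmr.phantom import signal_table

    table = signal_table(tissues, seq)
    assert np.array_equal(img.intensity, table[lm.labels])


def test_air_background_is_rayleigh(small_geometry):
    sigma = 0.7
    lm = m.build_label_map(small_geometry)
    tissues = m.tissue_preset("1.5T", "acute")
    seq = m.sequence_preset("bright", "1.5T", noise_sigma=sigma)
    img = m.render_image(lm, tissues, seq, seed=3)
    air = lm.mask(TissueClass.AIR)
    mean_air = img.intensity[air].mean()
    assert abs(mean_air - sigma * math.sqrt(math.pi / 2.0)) < 0.02 * sigma * math.sqrt(math.pi / 2.0)


def test_render_seeding_contract(small_geometry):
    lm = m.build_label_map(small_geometry)
    tissues = m.tissue_preset("1.5T", "acute")
    seq = m.sequence_preset("bright", "1.5T")
    a = m.render_image(lm, tissues, seq, seed=5).intensity
    b = m.render_image(lm, tissues, seq, seed=5).intensity
    c = m.render_image(lm, tissues, seq, seed=6).intensity
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_negative_noise_sigma_rejected():
    with pytest.raises(ValueError):
        m.SequenceParams(prep="bright", te=14.5, rr=857.0, flip_angle=18.0, noise_sigma=-1.0)


def test_lge_low_contrast_warns(small_geometry):
    lm = m.build_label_map(small_geometry)
    with pytest.warns(UserWarning, match="5-SD rule"):
        m.render_lge(lm, {"mu_mi": 55.0, "mu_remote": 50.0, "noise_sigma": 4.0}, seed=0)


def test_lge_noise_free_values(small_geometry):
    lm = m.build_label_map(small_geometry)
    img = m.render_lge(lm, {"noise_sigma": 0.0}, seed=0)
    assert np.all(img.intensity[lm.mask(TissueClass.MI)] == 100.0)
    assert np.all(img.intensity[lm.mask(TissueClass.REMOTE_MYO)] == 50.0)


# ---------------------------------------------------------------------------
# subjects


def test_stagnant_blood_follows_in_slice_formula(noise_free_subject):
    """Stagnant blood experiences both DIR pulses and so mimics tissue."""
    sim = noise_free_subject
    lm = sim["label_map"]
    dark = sim["dark"].intensity
    stag = lm.mask(TissueClass.BLOOD_STAGNANT)
    assert stag.any()
    blood = sim["tissues"][TissueClass.BLOOD_STAGNANT]
    seq = sim["sequences"]["dark"]
    expected_inslice = m.steady_state_signal(blood, seq, flowing=False)
    expected_flowing = m.steady_state_signal(blood, seq, flowing=True)
    assert np.allclose(dark[stag], expected_inslice)
    assert abs(expected_inslice - expected_flowing) > 1e-3


def test_chronic_iron_core_smaller_than_acute_at_same_seed():
    acute = m.simulate_subject(m.SubjectConfig(phase="acute"), seed=21)
    chronic = m.simulate_subject(m.SubjectConfig(phase="chronic"), seed=21)
    n_acute = acute["truth"].masks[TissueClass.IMH].sum()
    n_chronic = chronic["truth"].masks[TissueClass.IMH].sum()
    assert 0 < n_chronic < n_acute


def test_subject_truth_deterministic_under_seed():
    a = m.simulate_subject(m.SubjectConfig(), seed=33)
    b = m.simulate_subject(m.SubjectConfig(), seed=33)
    assert a["truth"].true_imh_extent == b["truth"].true_imh_extent
    assert np.array_equal(a["bright"].intensity, b["bright"].intensity)
    assert np.array_equal(a["dark"].intensity, b["dark"].intensity)


def test_true_extent_consistent_with_masks(noisy_subject):
    truth = noisy_subject["truth"]
    lm = noisy_subject["label_map"]
    n_imh = truth.masks[TissueClass.IMH].sum()
    n_myo = lm.myocardium_mask.sum()
    assert truth.true_imh_extent == pytest.approx(100.0 * n_imh / n_myo)
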