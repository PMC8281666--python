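"""Digital left-ventricle phantom and closed-form T2*-weighted signal model.

The phantom is a stack of short-axis slices: background air, an LV blood pool
(flowing plus an optional stagnant annulus adjacent to the infarct), remote
myocardium, an infarct (MI) sector and a hemorrhagic (IMH) core nested inside
the MI.  Paired bright-blood and DIR-prepared dark-blood T2*-weighted
magnitude images and an LGE-like image are rendered from the same label map
with a spoiled-gradient-echo signal model and Rician noise.

Signal model
------------
Bright-blood (no preparation), spoiled GRE at steady state with TR = RR::

    S = PD * sin(a) * (1 - E1) / (1 - E1 cos(a)) * exp(-TE / T2*),   E1 = exp(-RR / T1)

Dark-blood: a double-inversion-recovery (DIR) pair at the R-wave leaves

    Mprep = kappa * (1 - 2 eta_ns) * (1 - 2 eta_sel) * M0     (in-slice tissue,
                                                               stagnant blood)
    Mprep = kappa * (1 - 2 eta_ns) * M0                       (flowing blood,
                                                               replaced between
                                                               the two pulses)

which recovers for TI before the readout.  The preparation multiplies the
bright-blood signal by the recovered fraction::

    f(TI) = 1 - (1 - Mprep / M0) * exp(-TI / T1)

so for perfect inversions (eta = kappa = 1) and long TI the dark-blood signal
of in-slice tissue equals the bright-blood signal, and for any imperfect
preparation f < 1 — the lumped-magnetization account of the SNR penalty of
the DIR preparation.  Magnitude images are non-negative; Rician noise is the
magnitude of (S + g1, g2) with independent zero-mean Gaussians of SD
``noise_sigma``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .presets import (
    LGE_DEFAULTS,
    SEQUENCE_DEFAULTS,
    CHRONIC_IMH_ANGULAR_SCALE,
    CHRONIC_IMH_RADIAL_SCALE,
    Tissue,
    TissueClass,
    tissue_preset,
)

__all__ = [
    "PhantomGeometry",
    "SequenceParams",
    "LabelMap",
    "SimulatedImage",
    "GroundTruth",
    "SubjectConfig",
    "build_label_map",
    "steady_state_signal",
    "signal_table",
    "render_image",
    "render_lge",
    "ground_truth",
    "simulate_subject",
    "sequence_preset",
]


# ---------------------------------------------------------------------------
# geometry


@dataclass
class PhantomGeometry:
    """Geometry of the short-axis LV phantom (lengths in mm, angles in degrees).

    Angles are measured counter-clockwise from the anterior RV insertion
    reference ``ref_insertion_angle``; pixel membership is decided at pixel
    centers, 0-based row-major coordinates.  ``imh_rim_floor`` < 1 grades the
    hemorrhage severity from 1 at the core center down to the floor at the
    IMH boundary (1.0 = uniform core) following a power-law profile with
    exponent ``imh_rim_shape`` (2.0 = diffusion-like rim: severity falls off
    quadratically toward the boundary, so a sizable shell of the hemorrhage
    is only weakly hypointense); ``imh_slice_taper`` linearly shrinks the IMH
    angular span from the first to the last slice (1.0 = no taper).
    """

    grid_size: int = 192
    pixel_spacing: float = 1.0
    n_slices: int = 6
    lv_center: tuple[float, float] | None = None  # (row, col); None = grid center
    endo_radius: float = 15.0
    epi_radius: float = 25.0
    mi_angular_span: float = 100.0
    mi_center_angle: float = 45.0
    mi_transmurality: float = 0.8
    imh_angular_span: float = 50.0
    imh_radial_span: float = 0.6
    stagnant_layer_thickness: float = 2.0
    ref_insertion_angle: float = 90.0
    imh_rim_floor: float = 1.0
    imh_rim_shape: float = 2.0
    imh_slice_taper: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size too small")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.endo_radius <= 0 or self.epi_radius <= self.endo_radius:
            raise ValueError("need 0 < endo_radius < epi_radius")
        if not 0.0 <= self.mi_angular_span <= 360.0:
            raise ValueError("mi_angular_span must be in [0, 360]")
        if not 0.0 <= self.imh_angular_span <= self.mi_angular_span:
            raise ValueError("imh_angular_span must be in [0, mi_angular_span]")
        if not 0.0 < self.mi_transmurality <= 1.0:
            raise ValueError("mi_transmurality must be in (0, 1]")
        if not 0.0 <= self.imh_radial_span <= 1.0:
            raise ValueError("imh_radial_span must be in [0, 1]")
        if self.stagnant_layer_thickness < 0:
            raise ValueError("stagnant_layer_thickness must be >= 0")
        if not 0.0 < self.imh_rim_floor <= 1.0:
            raise ValueError("imh_rim_floor must be in (0, 1]")
        if self.imh_rim_shape <= 0:
            raise ValueError("imh_rim_shape must be positive")
        if not 0.0 < self.imh_slice_taper <= 1.0:
            raise ValueError("imh_slice_taper must be in (0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        if self.lv_center is not None:
            return tuple(self.lv_center)
        c = (self.grid_size - 1) / 2.0
        return (c, c)


def pixel_polar(
    grid_size: int, center: tuple[float, float], pixel_spacing: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Radius (mm) and angle (deg, CCW from the +column axis with the row axis
    pointing up, wrapped to [0, 360)) of every pixel center."""
    rows, cols = np.indices((grid_size, grid_size), dtype=float)
    dy = center[0] - rows  # image row grows downward; flip so angles run CCW
    dx = cols - center[1]
    r = np.hypot(dx, dy) * pixel_spacing
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    return r, theta


def _ang_dist(theta: np.ndarray, center: float) -> np.ndarray:
    """Absolute angular distance in degrees, wrapped to [0, 180]."""
    d = np.abs((theta - center + 180.0) % 360.0 - 180.0)
    return d


@dataclass
class LabelMap:
    """Integer tissue-class stack plus the per-pixel IMH severity map."""

    labels: np.ndarray  # (n_slices, N, N) uint8, TissueClass codes
    geometry: PhantomGeometry
    severity: np.ndarray | None = None  # (n_slices, N, N) float in [0,1], 0 outside IMH

    def mask(self, cls: TissueClass) -> np.ndarray:
        return self.labels == int(cls)

    @property
    def myocardium_mask(self) -> np.ndarray:
        return np.isin(self.labels, [TissueClass.REMOTE_MYO, TissueClass.MI, TissueClass.IMH])


def build_label_map(geometry: PhantomGeometry) -> LabelMap:
    """Rasterize the phantom geometry into a tissue-class stack.

    Myocardium is the annulus between the endo- and epicardial radii; the MI
    sector spans ``mi_angular_span`` around ``mi_center_angle`` to a radial
    depth of ``mi_transmurality`` from the endocardium; the IMH core is the
    nested sector emanating from the sub-endocardium; blood within
    ``stagnant_layer_thickness`` of the MI endocardial border is stagnant.
    """
    geometry.validate()
    g = geometry
    r, theta = pixel_polar(g.grid_size, g.center, g.pixel_spacing)
    wall = g.epi_radius - g.endo_radius
    mi_depth = g.mi_transmurality * wall
    imh_depth = g.imh_radial_span * mi_depth

    blood = r < g.endo_radius
    myo = (r >= g.endo_radius) & (r < g.epi_radius)
    d_mi = _ang_dist(theta, g.mi_center_angle)
    in_mi_sector = d_mi <= g.mi_angular_span / 2.0 if g.mi_angular_span > 0 else np.zeros_like(blood)
    mi = myo & in_mi_sector & (r < g.endo_radius + mi_depth)
    stagnant = (
        blood
        & in_mi_sector
        & (r >= g.endo_radius - g.stagnant_layer_thickness)
        & (g.stagnant_layer_thickness > 0)
    )

    labels = np.full((g.n_slices, g.grid_size, g.grid_size), int(TissueClass.AIR), dtype=np.uint8)
    severity = np.zeros_like(labels, dtype=float)
    base = np.full(blood.shape, int(TissueClass.AIR), dtype=np.uint8)
    base[blood] = int(TissueClass.BLOOD_FLOWING)
    base[stagnant] = int(TissueClass.BLOOD_STAGNANT)
    base[myo] = int(TissueClass.REMOTE_MYO)
    base[mi] = int(TissueClass.MI)

    for s in range(g.n_slices):
        frac = 1.0 if g.n_slices == 1 else s / (g.n_slices - 1)
        span_s = g.imh_angular_span * (1.0 + (g.imh_slice_taper - 1.0) * frac)
        sl = base.copy()
        if span_s > 0 and imh_depth > 0:
            d_imh = _ang_dist(theta, g.mi_center_angle)
            imh = mi & (d_imh <= span_s / 2.0) & (r < g.endo_radius + imh_depth)
            sl[imh] = int(TissueClass.IMH)
            if np.any(imh):
                u_ang = d_imh[imh] / (span_s / 2.0)
                u_rad = (r[imh] - g.endo_radius) / imh_depth
                u = np.clip(np.maximum(u_ang, u_rad), 0.0, 1.0)
                severity[s][imh] = g.imh_rim_floor + (1.0 - g.imh_rim_floor) * (
                    1.0 - u
                ) ** g.imh_rim_shape
        labels[s] = sl
    return LabelMap(labels=labels, geometry=g, severity=severity)


# ---------------------------------------------------------------------------
# sequences and signals


@dataclass
class SequenceParams:
    """Acquisition parameters of one T2*-weighted arm.

    ``prep`` is "bright" (no preparation) or "dark" (DIR).  Times in ms,
    flip angle in degrees.  ``eta_nonsel``/``eta_sel`` are the inversion
    efficiencies of the two adiabatic pulses, ``kappa`` a lumped preparation
    attenuation factor; all three are ignored by the bright arm.
    """

    prep: str
    te: float
    rr: float
    flip_angle: float
    ti: float | None = None
    eta_nonsel: float = 1.0
    eta_sel: float = 1.0
    kappa: float = 1.0
    noise_sigma: float = 0.0
    field: str = "1.5T"

    def __post_init__(self) -> None:
        if self.prep not in ("bright", "dark"):
            raise ValueError(f"prep must be 'bright' or 'dark', got {self.prep!r}")
        if self.te < 0 or self.rr <= 0:
            raise ValueError("need TE >= 0 and RR > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.prep == "dark":
            if self.ti is None or not 0 < self.ti < self.rr:
                raise ValueError("dark prep requires 0 < TI < RR")
            for name in ("eta_nonsel", "eta_sel"):
                v = getattr(self, name)
                if not 0.5 <= v <= 1.0:
                    raise ValueError(f"{name} must be in [0.5, 1]")
            if not 0.0 < self.kappa <= 1.0:
                raise ValueError("kappa must be in (0, 1]")


def sequence_preset(prep: str, field: str = "1.5T", **overrides) -> SequenceParams:
    """Sequence parameters for one arm at a field preset."""
    d = dict(SEQUENCE_DEFAULTS[field])
    d.update(overrides)
    if prep == "bright":
        d.pop("ti", None)
        d.pop("eta_nonsel", None)
        d.pop("eta_sel", None)
        d.pop("kappa", None)
    return SequenceParams(prep=prep, field=field, **d)


def dir_prep_factor(t1: float, seq: SequenceParams, flowing: bool = False) -> float:
    """Recovered longitudinal fraction f(TI) after the DIR preparation.

    In-slice tissue (and stagnant blood) experiences both inversions; blood
    flowing into the slice was replaced between the pulses and carries only
    the non-selective one.
    """
    p = seq.kappa * (1.0 - 2.0 * seq.eta_nonsel)
    if not flowing:
        p *= 1.0 - 2.0 * seq.eta_sel
    return 1.0 - (1.0 - p) * math.exp(-seq.ti / t1)


def steady_state_signal(tissue: Tissue, seq: SequenceParams, flowing: bool = False) -> float:
    """Noiseless magnitude signal of one tissue under one arm (see module docstring)."""
    if tissue.t1 <= 0 or tissue.t2star <= 0:
        raise ValueError("T1 and T2* must be positive")
    a = math.radians(seq.flip_angle)
    e1 = math.exp(-seq.rr / tissue.t1)
    ss = (1.0 - e1) / (1.0 - e1 * math.cos(a))
    s = tissue.proton_density * math.sin(a) * ss * math.exp(-seq.te / tissue.t2star)
    if seq.prep == "dark":
        s *= dir_prep_factor(tissue.t1, seq, flowing=flowing)
    return abs(s)


def signal_table(tissues: dict[TissueClass, Tissue], seq: SequenceParams) -> np.ndarray:
    """Per-class noiseless signal, indexed by TissueClass code."""
    table = np.zeros(max(int(c) for c in tissues) + 1)
    for cls, tis in tissues.items():
        table[int(cls)] = steady_state_signal(
            tis, seq, flowing=(cls == TissueClass.BLOOD_FLOWING)
        )
    return table


@dataclass
class SimulatedImage:
    """Non-negative magnitude image stack with acquisition metadata."""

    intensity: np.ndarray  # (n_slices, N, N) float
    meta: dict = dc_field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensity.shape


def _rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return noiseless.copy()
    g1 = rng.normal(0.0, sigma, size=noiseless.shape)
    g2 = rng.normal(0.0, sigma, size=noiseless.shape)
    return np.hypot(noiseless + g1, g2)


def render_image(
    label_map: LabelMap,
    tissues: dict[TissueClass, Tissue],
    seq: SequenceParams,
    seed: int,
    texture: np.ndarray | None = None,
) -> SimulatedImage:
    """Render one T2*-weighted arm from the label map.

    Pixels take the per-class noiseless signal; within the IMH core, a
    severity map (if graded) interpolates the decay rate R2* linearly between
    the remote-myocardium and IMH-core values, modelling the continuum of
    local iron concentration at the hemorrhage rim.  ``texture`` is an
    optional multiplicative field (intrinsic tissue heterogeneity; the same
    realization should be passed for both arms of a subject, since it models
    the tissue, not the acquisition).  Rician noise is applied as the
    magnitude of two Gaussian quadrature channels.
    """
    present = np.unique(label_map.labels)
    missing = [int(c) for c in present if int(c) not in {int(k) for k in tissues}]
    if missing:
        raise ValueError(f"label map contains classes without tissue entries: {missing}")
    table = signal_table(tissues, seq)
    noiseless = table[label_map.labels]

    sev = label_map.severity
    imh_mask = label_map.mask(TissueClass.IMH)
    if sev is not None and np.any(imh_mask) and not np.all(sev[imh_mask] == 1.0):
        imh_t, rem_t = tissues[TissueClass.IMH], tissues[TissueClass.REMOTE_MYO]
        r2s = 1.0 / rem_t.t2star + sev[imh_mask] * (1.0 / imh_t.t2star - 1.0 / rem_t.t2star)
        a = math.radians(seq.flip_angle)
        e1 = math.exp(-seq.rr / imh_t.t1)
        amp = imh_t.proton_density * math.sin(a) * (1.0 - e1) / (1.0 - e1 * math.cos(a))
        if seq.prep == "dark":
            amp *= dir_prep_factor(imh_t.t1, seq, flowing=False)
        noiseless[imh_mask] = np.abs(amp) * np.exp(-seq.te * r2s)

    if texture is not None:
        if texture.shape != noiseless.shape:
            raise ValueError("texture field must match the label-map shape")
        noiseless = noiseless * texture
    rng = np.random.default_rng(seed)
    img = _rician(noiseless, seq.noise_sigma, rng)
    return SimulatedImage(
        intensity=img,
        meta=dict(
            modality="T2sw", prep=seq.prep, te=seq.te, ti=seq.ti, field=seq.field,
            flip_angle=seq.flip_angle, noise_sigma=seq.noise_sigma, seed=seed,
        ),
    )


def render_lge(
    label_map: LabelMap,
    contrast_spec: dict | None = None,
    seed: int = 0,
    texture: np.ndarray | None = None,
) -> SimulatedImage:
    """Render the LGE-like image: infarct (incl. its hemorrhagic core) hyperintense.

    ``contrast_spec`` keys: mu_remote, mu_mi, mu_blood, mu_air, noise_sigma.
    Warns when the MI enhancement is below 5 channel-SDs of remote — the
    mean + 5 SD infarct rule would be unstable by construction.
    """
    spec = dict(LGE_DEFAULTS)
    if contrast_spec:
        spec.update(contrast_spec)
    if spec["noise_sigma"] < 0:
        raise ValueError("noise_sigma must be >= 0")
    if spec["mu_mi"] < spec["mu_remote"] + 5.0 * spec["noise_sigma"]:
        warnings.warn(
            "LGE MI enhancement below remote + 5*noise_sigma: the 5-SD rule will be unstable",
            stacklevel=2,
        )
    means = np.zeros(int(max(TissueClass)) + 1)
    means[int(TissueClass.AIR)] = spec["mu_air"]
    means[int(TissueClass.BLOOD_FLOWING)] = spec["mu_blood"]
    means[int(TissueClass.BLOOD_STAGNANT)] = spec["mu_blood"]
    means[int(TissueClass.REMOTE_MYO)] = spec["mu_remote"]
    means[int(TissueClass.MI)] = spec["mu_mi"]
    means[int(TissueClass.IMH)] = spec["mu_mi"]
    noiseless = means[label_map.labels]
    if texture is not None:
        noiseless = noiseless * texture
    rng = np.random.default_rng(seed)
    img = _rician(noiseless, spec["noise_sigma"], rng)
    return SimulatedImage(
        intensity=img,
        meta=dict(modality="LGE", noise_sigma=spec["noise_sigma"], seed=seed, **{
            k: spec[k] for k in ("mu_remote", "mu_mi", "mu_blood", "mu_air")
        }),
    )


# ---------------------------------------------------------------------------
# ground truth and subjects


@dataclass
class GroundTruth:
    """True per-class masks and the true IMH extent (% of LV myocardial volume)."""

    masks: dict[TissueClass, np.ndarray]
    true_imh_extent: float


def ground_truth(label_map: LabelMap) -> GroundTruth:
    masks = {cls: label_map.mask(cls) for cls in TissueClass}
    myo = label_map.myocardium_mask
    n_myo = int(myo.sum())
    if n_myo == 0:
        raise ValueError("phantom has no myocardium")
    extent = 100.0 * float(masks[TissueClass.IMH].sum()) / n_myo
    return GroundTruth(masks=masks, true_imh_extent=extent)


@dataclass
class SubjectConfig:
    """One simulated subject: field/phase presets plus geometry and overrides.

    The subject simulator enables the graded hemorrhage rim by default
    (``imh_rim_floor`` = 0.15) — rim pixels are weakly hypointense so their
    detection is noise-limited, as for real hemorrhage.  ``texture_sd`` sets
    intrinsic multiplicative tissue heterogeneity (one field per subject,
    shared by all modalities); like the thermal noise it is a stochastic
    image component, so a noise-free render (noise_sigma = 0) is fully
    deterministic and piecewise-ideal.  The chronic phase shrinks the IMH
    geometry (same seed, smaller residual iron core) and uses the chronic
    tissue preset.
    """

    field: str = "1.5T"
    phase: str = "acute"
    geometry: PhantomGeometry | None = None
    seq_overrides: dict = dc_field(default_factory=dict)
    lge_spec: dict = dc_field(default_factory=dict)
    imh_rim_floor: float = 0.15
    texture_sd: float = 0.05

    def resolved_geometry(self) -> PhantomGeometry:
        geom = self.geometry if self.geometry is not None else PhantomGeometry()
        geom = replace(geom, imh_rim_floor=self.imh_rim_floor)
        if self.phase == "chronic":
            geom = replace(
                geom,
                imh_angular_span=geom.imh_angular_span * CHRONIC_IMH_ANGULAR_SCALE,
                imh_radial_span=geom.imh_radial_span * CHRONIC_IMH_RADIAL_SCALE,
            )
        return geom


def simulate_subject(config: SubjectConfig, seed: int) -> dict:
    """Simulate one subject: slice-matched bright, dark and LGE images + truth.

    All three modalities share the label map; bright and dark share
    ``noise_sigma`` (matched readout).  The master seed is split
    deterministically per modality.
    """
    geom = config.resolved_geometry()
    label_map = build_label_map(geom)
    tissues = tissue_preset(config.field, config.phase)
    seq_bright = sequence_preset("bright", config.field, **config.seq_overrides)
    dark_over = dict(config.seq_overrides)
    seq_dark = sequence_preset("dark", config.field, **dark_over)
    s_bright, s_dark, s_lge, s_tex = np.random.SeedSequence(seed).generate_state(4) >> 1
    texture = None
    if config.texture_sd > 0 and seq_bright.noise_sigma > 0:
        tex_rng = np.random.default_rng(int(s_tex))
        texture = np.clip(
            1.0 + tex_rng.normal(0.0, config.texture_sd, size=label_map.labels.shape),
            0.0, None,
        )
    bright = render_image(label_map, tissues, seq_bright, int(s_bright), texture=texture)
    dark = render_image(label_map, tissues, seq_dark, int(s_dark), texture=texture)
    lge = render_lge(label_map, config.lge_spec, int(s_lge), texture=texture)
    return dict(
        bright=bright,
        dark=dark,
        lge=lge,
        truth=ground_truth(label_map),
        label_map=label_map,
        geometry=geom,
        tissues=tissues,
        sequences=dict(bright=seq_bright, dark=seq_dark),
        seed=seed,
    )
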