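"""End-to-end in-silico study: cohorts, two synthetic readers, result tables.

For every cell of the field (1.5T/3T) x MI-age (acute/chronic) design the
runner simulates a cohort of subjects with randomized phantom geometry,
quantifies both T2*-weighted arms with two synthetic readers, computes the
paired signal metrics, scores dark-blood segmental calls against bright-blood
calls, and emits agreement statistics (per-arm inter-reader ICC, dark-vs-
bright Bland-Altman, in-vivo vs ex-vivo regression).  Acute and chronic cells
share each subject's base geometry (the chronic iron core is a shrunken
version of the acute hemorrhage), mirroring a follow-up design.

Synthetic readers differ by their remote-ROI placement jitter and a small
perturbation (+/- 0.1 SD units by default) of the 5-SD and 2-SD thresholds;
a reader applies identical jitter to both arms of a subject.

Everything is deterministic under the master seed: child seeds are spawned
per (field, subject, phase, modality/reader) through ``SeedSequence``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import agreement, metrics, quantify, segments
from .phantom import PhantomGeometry, SubjectConfig, simulate_subject
from .presets import TissueClass

__all__ = [
    "GeometryRanges",
    "ReaderModel",
    "StudyConfig",
    "StudyReport",
    "draw_geometry",
    "run_study",
    "emulate_exvivo",
]


@dataclass
class GeometryRanges:
    """Uniform per-subject randomization ranges for the phantom geometry (mm/deg)."""

    endo_radius: tuple[float, float] = (13.0, 17.0)
    wall_thickness: tuple[float, float] = (8.0, 12.0)
    mi_angular_span: tuple[float, float] = (70.0, 120.0)
    mi_center_angle: tuple[float, float] = (20.0, 70.0)
    mi_transmurality: tuple[float, float] = (0.6, 0.9)
    imh_span_fraction: tuple[float, float] = (0.4, 0.8)  # of the MI span
    imh_radial_span: tuple[float, float] = (0.4, 0.7)
    imh_slice_taper: tuple[float, float] = (0.5, 0.9)


@dataclass
class ReaderModel:
    """Synthetic-reader behavior: ROI jitter plus threshold perturbation."""

    roi_width_deg: float = 60.0
    roi_rotation_jitter_deg: float = 20.0
    roi_width_jitter_deg: float = 10.0
    threshold_jitter_sd: float = 0.1  # +/- on the 5-SD and 2-SD multipliers


@dataclass
class StudyConfig:
    """Full study specification; serializable, reproducible under master_seed."""

    n_subjects: int = 10
    fields: tuple[str, ...] = ("1.5T", "3T")
    phases: tuple[str, ...] = ("acute", "chronic")
    grid_size: int = 192
    n_slices: int = 6
    master_seed: int = 20210715
    geometry_ranges: GeometryRanges = dc_field(default_factory=GeometryRanges)
    reader: ReaderModel = dc_field(default_factory=ReaderModel)
    n_readers: int = 2
    imh_rim_floor: float = 0.15
    texture_sd: float = 0.05
    min_core_pixels: int = 2
    n_segments: int = 6
    air_roi_size: int = 40
    exvivo_fine_factor: int = 2
    exclusions: tuple[tuple[int, int], ...] = ()
    seq_overrides: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyReport:
    """All result tables, keyed as written to disk (without .csv)."""

    tables: dict[str, pd.DataFrame]

    def __getitem__(self, key: str) -> pd.DataFrame:
        return self.tables[key]


def _child_seed(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] >> 1)


def draw_geometry(config: StudyConfig, field_idx: int, subject_idx: int) -> PhantomGeometry:
    """Randomized base (acute) geometry for one subject, deterministic in the seeds."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, 11, field_idx, subject_idx])
    )
    gr = config.geometry_ranges
    endo = rng.uniform(*gr.endo_radius)
    wall = rng.uniform(*gr.wall_thickness)
    mi_span = rng.uniform(*gr.mi_angular_span)
    return PhantomGeometry(
        grid_size=config.grid_size,
        n_slices=config.n_slices,
        endo_radius=endo,
        epi_radius=endo + wall,
        mi_angular_span=mi_span,
        mi_center_angle=rng.uniform(*gr.mi_center_angle),
        mi_transmurality=rng.uniform(*gr.mi_transmurality),
        imh_angular_span=mi_span * rng.uniform(*gr.imh_span_fraction),
        imh_radial_span=rng.uniform(*gr.imh_radial_span),
        imh_slice_taper=rng.uniform(*gr.imh_slice_taper),
    )


def emulate_exvivo(subject_config: SubjectConfig, fine_factor: int = 2) -> float:
    """Ex-vivo stand-in: noise-free, finer-grid re-render and re-quantification.

    The same phantom is rasterized at ``fine_factor`` x the in-plane
    resolution, rendered without noise and segmented with unjittered readers;
    the measured extent is the fine-grid truth.
    """
    if fine_factor < 1:
        raise ValueError("fine_factor must be >= 1")
    geom = subject_config.geometry if subject_config.geometry is not None else PhantomGeometry()
    fine_geom = replace(
        geom,
        grid_size=geom.grid_size * fine_factor,
        pixel_spacing=geom.pixel_spacing / fine_factor,
        lv_center=None,
    )
    over = dict(subject_config.seq_overrides)
    over["noise_sigma"] = 0.0
    lge_spec = dict(subject_config.lge_spec)
    lge_spec["noise_sigma"] = 0.0
    cfg = replace(
        subject_config, geometry=fine_geom, seq_overrides=over, lge_spec=lge_spec
    )
    sim = simulate_subject(cfg, seed=0)
    myo = sim["label_map"].myocardium_mask
    seg = quantify.segment_subject(sim["lge"], sim["bright"], myo)
    return seg.imh_extent_pct


def _reader_params(config: StudyConfig, field_idx: int, subject_idx: int,
                   phase_idx: int, reader_idx: int) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.master_seed, 23, field_idx, subject_idx, reader_idx]
    ))
    tj = config.reader.threshold_jitter_sd
    return dict(
        jitter_seed=_child_seed(config.master_seed, 29, field_idx, subject_idx, reader_idx),
        mi_k=5.0 + rng.uniform(-tj, tj),
        imh_k=2.0 + rng.uniform(-tj, tj),
    )


def _quantify_arm(sim, arm: str, reader: dict, config: StudyConfig):
    myo = sim["label_map"].myocardium_mask
    roi_kwargs = dict(
        width_deg=config.reader.roi_width_deg,
        rotation_jitter_deg=config.reader.roi_rotation_jitter_deg,
        width_jitter_deg=config.reader.roi_width_jitter_deg,
    )
    return quantify.segment_subject(
        sim["lge"], sim[arm], myo,
        jitter_seed=reader["jitter_seed"],
        mi_k=reader["mi_k"], imh_k=reader["imh_k"],
        min_core_pixels=config.min_core_pixels,
        roi_kwargs=roi_kwargs,
    )


def process_subject(sim, readers: list[dict], config: StudyConfig) -> dict:
    """Quantify one simulated subject with all readers; return the flat record."""
    myo = sim["label_map"].myocardium_mask
    air = quantify.air_roi_mask(sim["bright"].shape, config.air_roi_size)
    segs = {arm: [_quantify_arm(sim, arm, r, config) for r in readers]
            for arm in ("bright", "dark")}

    rec: dict = dict(true_extent=sim["truth"].true_imh_extent)
    for arm in ("bright", "dark"):
        exts = [s.imh_extent_pct for s in segs[arm]]
        rec[f"extent_{arm}"] = float(np.mean(exts))
        for i, e in enumerate(exts):
            rec[f"extent_{arm}_r{i + 1}"] = e

    snr, cnr, cov_db, cov_bb = [], [], [], []
    air_b = quantify.region_stats(sim["bright"], air)
    air_d = quantify.region_stats(sim["dark"], air)
    noise_free = air_b.sd_si == 0 or air_d.sd_si == 0
    for i in range(len(readers)):
        sb, sd_ = segs["bright"][i], segs["dark"][i]
        roi_b = sb.remote_stats
        roi_d = sd_.remote_stats
        cov_bb.append(metrics.cov(roi_b))
        cov_db.append(metrics.cov(roi_d))
        if noise_free:
            continue  # sigma_air = 0: Eq. 1-2 ratios are undefined
        snr.append(metrics.relative_snr(roi_d, air_d, roi_b, air_b))
        if sb.imh_mask.any() and sd_.imh_mask.any():
            imh_b = quantify.region_stats(sim["bright"], sb.imh_mask)
            imh_d = quantify.region_stats(sim["dark"], sd_.imh_mask)
            cnr.append(metrics.relative_cnr(roi_d, imh_d, air_d, roi_b, imh_b, air_b))
    rec["relative_snr_pct"] = float(np.mean(snr)) if snr else float("nan")
    rec["relative_cnr_pct"] = float(np.mean(cnr)) if cnr else float("nan")
    rec["cov_bb"] = float(np.mean(cov_bb))
    rec["cov_db"] = float(np.mean(cov_db))
    rec["cov_increase_pct"] = (
        100.0 * (rec["cov_db"] - rec["cov_bb"]) / rec["cov_bb"]
        if rec["cov_bb"] > 0 else float("nan")
    )
    rec["extent_reduction_pct"] = (
        100.0 * (rec["extent_bright"] - rec["extent_dark"]) / rec["extent_bright"]
        if rec["extent_bright"] > 0 else float("nan")
    )

    # segmental diagnostics from reader 1, dark vs bright
    geom = sim["geometry"]
    part = segments.partition_stack(
        myo, geom.center, geom.ref_insertion_angle, config.n_segments
    )
    excl = set(map(tuple, config.exclusions))
    meas = {
        arm: segments.call_segments(
            segments.segment_measurements(segs[arm][0].imh_mask, part),
            exclusions=excl,
        )
        for arm in ("bright", "dark")
    }
    cont = segments.contingency(meas["dark"], meas["bright"])
    keep = ~meas["dark"]["excluded"]
    dx = segments.dx_summary(
        cont,
        meas["dark"].loc[keep, "hypo_fraction"].to_numpy(),
        meas["bright"].loc[keep, "positive"].to_numpy(),
    )
    rec.update(
        sensitivity=dx.sensitivity, specificity=dx.specificity,
        accuracy=dx.accuracy, auc=dx.auc,
        tp=cont.tp, fp=cont.fp, tn=cont.tn, fn=cont.fn,
    )
    return rec


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Run the full study; optionally write all tables and a run log to out_dir."""
    rows = []
    for fi, field in enumerate(config.fields):
        for si in range(config.n_subjects):
            base_geom = draw_geometry(config, fi, si)
            exvivo_cache: dict[str, float] = {}
            for pi, phase in enumerate(config.phases):
                sub_cfg = SubjectConfig(
                    field=field, phase=phase, geometry=base_geom,
                    imh_rim_floor=config.imh_rim_floor,
                    texture_sd=config.texture_sd,
                    seq_overrides=dict(config.seq_overrides),
                )
                seed = _child_seed(config.master_seed, 3, fi, si, pi)
                sim = simulate_subject(sub_cfg, seed)
                readers = [
                    _reader_params(config, fi, si, pi, r) for r in range(config.n_readers)
                ]
                rec = process_subject(sim, readers, config)
                rec.update(field=field, phase=phase, subject=si, seed=seed)
                if phase not in exvivo_cache:
                    exvivo_cache[phase] = emulate_exvivo(sub_cfg, config.exvivo_fine_factor)
                rec["exvivo_extent"] = exvivo_cache[phase]
                rows.append(rec)
    per_subject = pd.DataFrame(rows)

    tables = {"per_subject": per_subject}
    tables.update(_summaries(per_subject, config))
    report = StudyReport(tables=tables)
    if out_dir is not None:
        _write_report(report, config, Path(out_dir))
    return report


def _cell_groups(df: pd.DataFrame):
    return df.groupby(["field", "phase"], sort=True)


def _summaries(per_subject: pd.DataFrame, config: StudyConfig) -> dict[str, pd.DataFrame]:
    sig_rows, ext_rows, ba_rows, icc_rows, dx_rows, reg_rows = [], [], [], [], [], []
    for (field, phase), g in _cell_groups(per_subject):
        cell = dict(field=field, phase=phase, n=len(g))
        sig_rows.append(dict(
            cell,
            relative_snr_mean=g["relative_snr_pct"].mean(),
            relative_snr_sd=g["relative_snr_pct"].std(),
            relative_cnr_mean=g["relative_cnr_pct"].mean(),
            relative_cnr_sd=g["relative_cnr_pct"].std(),
            cov_bright_mean=g["cov_bb"].mean(),
            cov_dark_mean=g["cov_db"].mean(),
            cov_increase_pct_mean=g["cov_increase_pct"].mean(),
            cov_increase_pct_sd=g["cov_increase_pct"].std(),
        ))
        t_ext = sps.ttest_rel(g["extent_bright"], g["extent_dark"])
        ext_rows.append(dict(
            cell,
            true_extent_mean=g["true_extent"].mean(),
            extent_bright_mean=g["extent_bright"].mean(),
            extent_bright_sd=g["extent_bright"].std(),
            extent_dark_mean=g["extent_dark"].mean(),
            extent_dark_sd=g["extent_dark"].std(),
            reduction_pct_mean=g["extent_reduction_pct"].mean(),
            reduction_pct_sd=g["extent_reduction_pct"].std(),
            p_paired_t=float(t_ext.pvalue),
        ))
        ba = agreement.bland_altman(g["extent_bright"].to_numpy(), g["extent_dark"].to_numpy())
        ba_rows.append(dict(cell, bias=ba.bias, sd_diff=ba.sd_diff,
                            loa_low=ba.loa_low, loa_high=ba.loa_high))
        if config.n_readers == 2 and len(g) >= 3:
            for arm in ("bright", "dark"):
                pairs = g[[f"extent_{arm}_r1", f"extent_{arm}_r2"]].to_numpy()
                res = agreement.icc(pairs)
                icc_rows.append(dict(cell, arm=arm, icc=res.icc,
                                     ci_low=res.ci_low, ci_high=res.ci_high))
        dx_rows.append(dict(
            cell,
            sensitivity_mean=g["sensitivity"].mean(), sensitivity_sd=g["sensitivity"].std(),
            specificity_mean=g["specificity"].mean(), specificity_sd=g["specificity"].std(),
            accuracy_mean=g["accuracy"].mean(), accuracy_sd=g["accuracy"].std(),
            auc_mean=g["auc"].mean(), auc_sd=g["auc"].std(),
        ))
        for arm in ("bright", "dark"):
            try:
                reg = agreement.extent_regression(
                    g["exvivo_extent"].to_numpy(), g[f"extent_{arm}"].to_numpy()
                )
            except ValueError:  # cells too small or degenerate for OLS
                continue
            reg_rows.append(dict(cell, arm=arm, slope=reg.slope,
                                 intercept=reg.intercept, r_squared=reg.r_squared))
    return {
        "summary_signal": pd.DataFrame(sig_rows),
        "summary_extent": pd.DataFrame(ext_rows),
        "bland_altman": pd.DataFrame(ba_rows),
        "icc": pd.DataFrame(icc_rows),
        "diagnostic": pd.DataFrame(dx_rows),
        "exvivo_regression": pd.DataFrame(reg_rows),
    }


def _write_report(report: StudyReport, config: StudyConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.10g")
    import json

    from .presets import SEQUENCE_DEFAULTS, LGE_DEFAULTS, tissue_preset

    log = {
        "config": config.to_dict(),
        "sequence_defaults": SEQUENCE_DEFAULTS,
        "lge_defaults": LGE_DEFAULTS,
        "tissue_presets": {
            f"{f}-{p}": {
                TissueClass(c).name: dataclasses.asdict(t)
                for c, t in tissue_preset(f, p).items()
            }
            for f in config.fields for p in config.phases
        },
    }
    with open(out_dir / "run.log", "w") as fh:
        # json round-trip turns tuples/dataclass leftovers into plain YAML types
        yaml.safe_dump(json.loads(json.dumps(log)), fh, sort_keys=True)
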