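"""Relative SNR, relative CNR and COV for paired dark/bright acquisitions.

Each arm self-normalizes by the SD of its own background air (sigma_air), so
both relative metrics are invariant to a global intensity rescaling of either
arm alone::

    Relative SNR = 100 * (SI_remote_DB / sigma_air_DB) / (SI_remote_BB / sigma_air_BB)
    Relative CNR = 100 * ((SI_remote_DB - SI_IMH_DB) / sigma_air_DB)
                       / ((SI_remote_BB - SI_IMH_BB) / sigma_air_BB)
    COV          = sigma / SI   (over one region of interest)

sigma_air is taken as the raw SD of the magnitude image over the air ROI,
without a Rayleigh correction: the relative metrics are ratios of like
quantities, so the Rayleigh factor cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

from .quantify import RegionStats

__all__ = ["MetricRecord", "relative_snr", "relative_cnr", "cov", "metric_record"]


@dataclass
class MetricRecord:
    """Eq.-level inputs and derived metrics for one paired acquisition."""

    si_remote_db: float
    si_remote_bb: float
    si_imh_db: float
    si_imh_bb: float
    sigma_air_db: float
    sigma_air_bb: float
    relative_snr_pct: float
    relative_cnr_pct: float
    cov_db: float
    cov_bb: float


def _check_air(stats: RegionStats, arm: str) -> None:
    if stats.sd_si <= 0:
        raise ValueError(f"air ROI SD is zero in the {arm} arm; SNR/CNR undefined")


def relative_snr(
    remote_db: RegionStats,
    air_db: RegionStats,
    remote_bb: RegionStats,
    air_bb: RegionStats,
) -> float:
    """Dark-to-bright remote-myocardium SNR ratio, in percent."""
    _check_air(air_db, "dark")
    _check_air(air_bb, "bright")
    return 100.0 * (remote_db.mean_si / air_db.sd_si) / (remote_bb.mean_si / air_bb.sd_si)


def relative_cnr(
    remote_db: RegionStats,
    imh_db: RegionStats,
    air_db: RegionStats,
    remote_bb: RegionStats,
    imh_bb: RegionStats,
    air_bb: RegionStats,
) -> float:
    """Dark-to-bright IMH-vs-remote CNR ratio, in percent."""
    _check_air(air_db, "dark")
    _check_air(air_bb, "bright")
    contrast_bb = remote_bb.mean_si - imh_bb.mean_si
    if contrast_bb == 0:
        raise ValueError("bright-arm IMH contrast is zero; relative CNR undefined")
    contrast_db = remote_db.mean_si - imh_db.mean_si
    return 100.0 * (contrast_db / air_db.sd_si) / (contrast_bb / air_bb.sd_si)


def cov(stats: RegionStats) -> float:
    """Coefficient of variation of a region: SD / mean."""
    if stats.mean_si == 0:
        raise ValueError("zero region mean; COV undefined")
    return stats.sd_si / stats.mean_si


def metric_record(
    remote_db: RegionStats,
    imh_db: RegionStats,
    air_db: RegionStats,
    remote_bb: RegionStats,
    imh_bb: RegionStats,
    air_bb: RegionStats,
) -> MetricRecord:
    """Assemble the full per-subject metric record from region statistics."""
    return MetricRecord(
        si_remote_db=remote_db.mean_si,
        si_remote_bb=remote_bb.mean_si,
        si_imh_db=imh_db.mean_si,
        si_imh_bb=imh_bb.mean_si,
        sigma_air_db=air_db.sd_si,
        sigma_air_bb=air_bb.sd_si,
        relative_snr_pct=relative_snr(remote_db, air_db, remote_bb, air_bb),
        relative_cnr_pct=relative_cnr(remote_db, imh_db, air_db, remote_bb, imh_bb, air_bb),
        cov_db=cov(remote_db),
        cov_bb=cov(remote_bb),
    )
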