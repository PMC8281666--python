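"""Shared plumbing for the numbered analysis drivers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

import imhcmr as m

ROOT = Path(__file__).resolve().parents[1]
STUDY_DIR = ROOT / "results" / "study"


def study_config() -> m.StudyConfig:
    """The cohort analyzed by scripts 02-05: 10 subjects per cell (the
    clinical study's per-field scale), default presets and master seed."""
    return m.StudyConfig(n_subjects=10)


def ensure_study() -> dict[str, pd.DataFrame]:
    """Run the study once and cache all tables under results/study/."""
    if not (STUDY_DIR / "per_subject.csv").exists():
        print("running the in-silico study (first call, ~10 s) ...")
        m.run_study(study_config(), out_dir=STUDY_DIR)
    return {
        p.stem: pd.read_csv(p) for p in sorted(STUDY_DIR.glob("*.csv"))
    }
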