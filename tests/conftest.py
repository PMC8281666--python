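"""Shared fixtures: small phantoms for unit tests, one full-size cohort run."""

from __future__ import annotations

import numpy as np
import pytest

import imhcmr as m


@pytest.fixture(scope="session")
def default_geometry() -> m.PhantomGeometry:
    return m.PhantomGeometry()


@pytest.fixture(scope="session")
def small_geometry() -> m.PhantomGeometry:
    """Coarse phantom for fast unit tests."""
    return m.PhantomGeometry(grid_size=96, n_slices=2, endo_radius=12.0, epi_radius=20.0)


@pytest.fixture(scope="session")
def noise_free_subject() -> dict:
    """Deterministic render: no thermal noise, no tissue texture."""
    cfg = m.SubjectConfig(
        geometry=m.PhantomGeometry(grid_size=128, n_slices=3),
        seq_overrides={"noise_sigma": 0.0},
        lge_spec={"noise_sigma": 0.0},
        texture_sd=0.0,
    )
    return m.simulate_subject(cfg, seed=7)


@pytest.fixture(scope="session")
def noisy_subject() -> dict:
    """Default stochastic subject at full grid."""
    return m.simulate_subject(m.SubjectConfig(), seed=11)


@pytest.fixture(scope="session")
def cohort_report() -> m.StudyReport:
    """Full study at the scale the directional findings are stated for:
    20 subjects per field x phase cell, default presets and master seed."""
    cfg = m.StudyConfig(n_subjects=20)
    return m.run_study(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
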