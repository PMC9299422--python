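"""Shared fixtures: small synthetic cohorts and segments, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import holterpaf as hp


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 patients x 5 min, balanced, strong morphology effect; in memory."""
    cfg = hp.SimConfig(
        n_patients=12, paf_fraction=0.5, duration_s=300.0,
        p_wave_effect=0.3, sve_rate_control=4.0, sve_rate_paf=10.0,
        ve_rate=2.0, seed=42,
    )
    manifest, data = hp.generate_cohort(cfg)
    return cfg, manifest, data


@pytest.fixture(scope="session")
def quiet_recording():
    """One 70-s ectopy-free recording with its annotations."""
    cfg = hp.SimConfig(
        n_patients=1, paf_fraction=0.0, duration_s=70.0,
        sve_rate_control=0.0, sve_rate_paf=0.0, ve_rate=0.0, seed=9,
    )
    _, data = hp.generate_cohort(cfg)
    return data["P0000"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
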