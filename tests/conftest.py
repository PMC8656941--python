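"""Shared fixtures: small synthetic cohorts generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from megrest import SimSpec, CouplingSpec, gen_source_timeseries

FS = 250.0
EPOCH_LEN = 4096


@pytest.fixture(scope="session")
def small_spec() -> SimSpec:
    """One CN subject, 8 regions, ~17 candidate epochs, planted pathology."""
    return SimSpec(
        n_subjects_per_group={"CN": 1, "CI": 0},
        n_regions=8,
        fs=FS,
        duration=280.0,
        epoch_len=EPOCH_LEN,
        occipital_idx=(0, 1, 2),
        coupling_pairs=(CouplingSpec(4, 6, 0.6, "alpha2"),),
        mixing_strength=0.2,
        artifact_rate=0.10,
        drowsy_rate=0.10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return gen_source_timeseries(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
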