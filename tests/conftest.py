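"""Shared fixtures: calibrated generator configs and small cohorts."""

from dataclasses import replace

import numpy as np
import pytest

from ramanff.preprocess import preprocess_set
from ramanff.spectra import Spectrum, WavenumberGrid
from ramanff.synthetic import (
    GroupEffect,
    calibrated_config,
    default_config,
    generate_dataset,
)
from ramanff.zones import ZONE_A, Zone


@pytest.fixture(scope="session")
def pcos_calibrated():
    """PCOS-task generator calibrated to the printed zone means (computed once)."""
    return calibrated_config("pcos")


@pytest.fixture(scope="session")
def small_pcos_cohort(pcos_calibrated):
    """Preprocessed 30+30 cohort from the calibrated generator."""
    cfg = replace(pcos_calibrated, n_per_group=30, seed=11)
    return preprocess_set(generate_dataset(cfg, "pcos"))


@pytest.fixture(scope="session")
def separable_cohort():
    """Deterministic two-class cohort with a large disjoint peak effect.

    Zero noise and a 2x gain on the 993-1165 zone for the positive class
    make the classes linearly separable by construction.
    """
    cfg = default_config(
        "blastocyst",
        n_per_group=10,
        noise_sd=0.0,
        replicate_jitter_sd=0.0,
        sample_gain_sd=0.0,
        baseline_tilt_sd=0.0,
        effects=(("HQ", GroupEffect(Zone(*ZONE_A), 2.0)),),
    )
    return preprocess_set(generate_dataset(cfg, "blastocyst"))


@pytest.fixture
def flat_spectrum():
    grid = WavenumberGrid(600, 1800)
    return Spectrum(grid, np.full(grid.n_points, 3.0))
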