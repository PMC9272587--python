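"""Shared fixtures: desk-scale synthetic cohorts reused across test modules.

The small cohorts use a reduced grid (16^3), shorter runs (120 s / 60
volumes) and a matching smaller dose mask so the full signal chain stays
fast; tests that depend on the full-scale study conditions build their own
cohorts at the default configuration.
"""

import numpy as np
import pytest

import alphafield as af
from alphafield.synthetic import synthetic_roi_specs


def small_config(**overrides) -> af.SimConfig:
    base = dict(
        n_subjects=3,
        grid_shape=(16, 16, 16),
        n_coupled_voxels=150,
        run_duration=120.0,
        n_volumes=60,
    )
    base.update(overrides)
    return af.SimConfig(**base)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Two subjects at default noise levels on the reduced grid."""
    cfg = small_config(n_subjects=2)
    records, truth = af.generate_cohort(cfg, seed=42)
    return cfg, records, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Six subjects with response and EEG-background noise switched off."""
    cfg = small_config(n_subjects=6, noise_sd=0.0, eeg_background_sd=0.0)
    records, truth = af.generate_cohort(cfg, seed=7)
    return cfg, records, truth


@pytest.fixture(scope="session")
def noiseless_result(noiseless_cohort):
    cfg, records, truth = noiseless_cohort
    pcfg = af.PipelineConfig(
        k_voxels=cfg.n_coupled_voxels, roi_specs=synthetic_roi_specs(cfg)
    )
    return af.run_pipeline(records, pcfg), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
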