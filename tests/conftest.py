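"""Shared fixtures: small simulated sessions and layouts, built once per run."""

from dataclasses import replace

import numpy as np
import pytest

from presacc.layout import make_layout
from presacc.pipeline import AnalysisParams, test_scale_sim_config
from presacc.simulate import default_kernels, simulate_session


@pytest.fixture(scope="session")
def small_layout():
    return make_layout(n_sites=10, symmetric=True, seed=0)


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Very small session for unit tests: 6 sites, 24/12/12 trials."""
    return test_scale_sim_config(
        seed=101, n_sites=6,
        trials_per_condition={"saccade_stimulus": 24, "saccade_only": 12,
                              "stimulus_only": 12})


@pytest.fixture(scope="session")
def tiny_session(tiny_sim_config):
    return simulate_session(tiny_sim_config, 0)


@pytest.fixture(scope="session")
def clean_session_config():
    """Zero-noise, grid-snapped, non-negative kernels: exact-arithmetic setup."""
    kern = default_kernels(0.0)
    kern["saccade"] = replace(kern["saccade"], nonneg=True)
    kern["stimulus"] = replace(kern["stimulus"], lateralization="bilateral")
    cfg = test_scale_sim_config(seed=7, n_sites=8, residual_amplitude=0.0)
    return replace(cfg, kernels=kern, noise_white_sd=0.0, noise_pink_sd=0.0,
                   gaze_noise_sd=0.0, microsaccade_rate=0.0, snap_to_grid=True,
                   trials_per_condition={"saccade_stimulus": 40,
                                         "saccade_only": 20,
                                         "stimulus_only": 40})


@pytest.fixture(scope="session")
def clean_session(clean_session_config):
    return simulate_session(clean_session_config, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_params():
    """Truth-event analysis parameters for the simulation studies."""
    return AnalysisParams(epoch_window=(-0.5, 0.62), n_draws=30,
                          use_truth_events=True, apply_notch=False, seed=0)
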