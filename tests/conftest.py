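"""Shared fixtures: synthetic trials reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from balancegait.pipeline import analyze_trial
from balancegait.synthetic import WalkerConfig, generate_trial

NOISELESS = dict(
    marker_noise_sd=0.0,
    angle_noise_sd=0.0,
    emg_noise_sd=0.0,
    moment_noise_sd=0.0,
    fp_noise_sd=0.0,
    gap_rate=0.0,
)


@pytest.fixture(scope="session")
def noiseless_trial():
    """One noiseless trial (CoM variability kept: it drives the placement law)."""
    cfg = WalkerConfig(seed=11, **NOISELESS)
    return generate_trial(cfg, n_steps=120)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_trial):
    bundle, truth = noiseless_trial
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_trial(bundle), truth


@pytest.fixture(scope="session")
def noisy_trial():
    cfg = WalkerConfig(seed=5)
    return generate_trial(cfg, n_steps=120)


@pytest.fixture(scope="session")
def noisy_analysis(noisy_trial):
    bundle, truth = noisy_trial
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_trial(bundle), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
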