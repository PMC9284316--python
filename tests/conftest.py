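"""Shared fixtures: ground-truth condition, noise-free trajectory, noisy data."""

import warnings

import numpy as np
import pytest

from diurnalcn import (
    default_condition_specs,
    sample_replicates,
    simulate_condition,
)

# negative-clip warnings from near-zero pools are expected solver slack
warnings.filterwarnings("ignore", message="clipped .* negative state")


@pytest.fixture(scope="session")
def col0_spec():
    return default_condition_specs()["col0_ambient"]


@pytest.fixture(scope="session")
def col0_truth(col0_spec):
    """Noise-free ground-truth trajectory and drivers for Col-0 at ambient CO2."""
    trajectory, drivers = simulate_condition(col0_spec)
    return trajectory, drivers


@pytest.fixture(scope="session")
def col0_observations(col0_truth):
    """Noisy observations (cv = 0.05, n = 5) for the Col-0 ambient cycle."""
    trajectory, _ = col0_truth
    obs, _ = sample_replicates(trajectory, n=5, cv=0.05, seed=0)
    return obs


@pytest.fixture
def rng():
    return np.random.default_rng(0)
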