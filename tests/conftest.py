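import numpy as np
import pandas as pd
import pytest

from sxmerge.data_model import ReflectionGroup
from sxmerge.synthetic_data import SimulationConfig, simulate_dataset
from sxmerge.workflows import correct_and_group


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A few thousand measurements; enough structure for pipeline tests."""
    return SimulationConfig(
        n_images=200, reflections_per_image=15, n_unique=300,
        wilson_mean=500.0, g_range=(0.8, 1.2), b_range=(0.0, 4.0),
        partiality_law="beta", background_var=25.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_groups(small_dataset):
    return correct_and_group(small_dataset.measurements, small_dataset.images)


def random_groups(rng, n_groups=1000, max_n=8, scale=100.0):
    """Random corrected reflection groups for merge/oracle tests."""
    groups = []
    for g in range(n_groups):
        n = int(rng.integers(1, max_n + 1))
        groups.append(ReflectionGroup(
            hkl=(g, 0, 0),
            intensities=rng.normal(scale, scale / 3, n),
            sigmas=rng.uniform(1.0, 20.0, n),
            stol2=rng.uniform(0.0, 0.05, n),
        ))
    return groups


@pytest.fixture
def random_group_set(rng):
    return random_groups(rng)
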