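import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gingerspec as gs

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down campaign for fast unit tests: fewer samples, fewer
    bands, small cubes — same statistical structure as the defaults."""
    return gs.SyntheticConfig(n_samples=30, n_bands=60, cube_rows=8, cube_cols=8, seed=7)


@pytest.fixture(scope="session")
def small_samples(small_config):
    return gs.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_samples):
    return gs.extract_dataset(small_samples)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return gs.split_dataset(small_dataset, gs.SplitSpec())
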