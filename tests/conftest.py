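import numpy as np
import pytest
from hypothesis import settings

from tamuc.simulate import SimConfig, simulate_cohort_pair, synthetic_catalog

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def catalog():
    return synthetic_catalog(seed=11)


@pytest.fixture(scope="session")
def small_pair(catalog):
    """A small simulated cohort pair with planted subtype truth."""
    config = SimConfig(n_exposed=12, n_control=40, seed=11)
    exposed, control, truth = simulate_cohort_pair(config, catalog, with_truth=True)
    return config, exposed, control, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
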