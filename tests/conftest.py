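import numpy as np
import pytest
from hypothesis import settings

from hdma import SimulationConfig, simulate_dataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_binary_dataset():
    """One default-design binary dataset, small enough for fast pipeline runs."""
    return simulate_dataset(SimulationConfig(n=300, k=100, rho=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
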