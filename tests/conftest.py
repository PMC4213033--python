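import numpy as np
import pytest

from invasionfit import SimulationConfig, simulate_invasion_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact seeded invasion dataset shared across pipeline tests."""
    cfg = SimulationConfig(n_sites=120, seed=42)
    return simulate_invasion_dataset(cfg)
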