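import numpy as np
import pytest

from squigglecall.squiggle_sim import PoreModel, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pore():
    return PoreModel()


@pytest.fixture(scope="session")
def small_dataset(pore):
    """A small pool of simulated reads shared across tests."""
    return simulate_dataset(40, pore, min_len=150, max_len=300, seed=99)
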