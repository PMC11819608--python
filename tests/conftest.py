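import numpy as np
import pytest

from isodex import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structurally complete simulated dataset."""
    return simulate_dataset(SimulationConfig(n_genes=8, j1=4, j2=4, seed=11))
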