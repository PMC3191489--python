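import numpy as np
import pytest

from initsteps import SimulationConfig, simulate_cell_traces, simulate_intervals


@pytest.fixture(scope="session")
def weak_sample():
    """A large seeded interval sample from the weak-induction 2-step model."""
    return simulate_intervals(2, [1116.0, 1116.0], 20_000, seed=11)


@pytest.fixture(scope="session")
def two_step_unequal_sample():
    return simulate_intervals(2, [1000.0, 500.0], 20_000, seed=12)


@pytest.fixture(scope="session")
def weak_traces():
    cfg = SimulationConfig(n_cells=60, seed=5)
    return simulate_cell_traces(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
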