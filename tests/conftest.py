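import numpy as np
import pytest

from fractumor import (
    SimulationConfig,
    baseline_parameters,
    initial_state,
)


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture(scope="session")
def y0():
    return initial_state().to_array()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def short_config():
    """10-day horizon for solver cross-checks."""
    return SimulationConfig(duration=10.0, n_points=11)
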