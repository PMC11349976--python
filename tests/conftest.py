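import numpy as np
import pytest

from oscillear.grid import SimGrid


@pytest.fixture(scope="session")
def unit_grid():
    """50 cycles of a unit-frequency oscillator at 200 samples/cycle."""
    return SimGrid(0.0, 50.0, 0.005)


@pytest.fixture(scope="session")
def fine_grid():
    return SimGrid(0.0, 20.0, 0.001)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
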