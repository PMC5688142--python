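import numpy as np
import pytest

from optoloop import CellParams, CellState


@pytest.fixture
def params():
    return CellParams()


@pytest.fixture
def dark_state(params):
    """A cell at the no-light steady state."""
    return CellState(H=0.0, E=params.E_bar, F=params.f0 / params.gamma)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
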