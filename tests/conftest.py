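import numpy as np
import pytest

from usmcsim.model import CellState, find_equilibrium
from usmcsim.parameters import Params


@pytest.fixture(scope="session")
def params():
    return Params.default()


@pytest.fixture(scope="session")
def equilibrium(params) -> CellState:
    """Resting state of the default model (stored values, verified once)."""
    return find_equilibrium(params, relax_ms=60000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
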