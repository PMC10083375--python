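import numpy as np
import pytest

from vcapsim import MechParams, TimeGrid
from vcapsim.spikegen import IAFParams
from vcapsim.vcap import KernelParams


@pytest.fixture
def mech():
    return MechParams()


@pytest.fixture
def iaf():
    return IAFParams()


@pytest.fixture
def kern():
    return KernelParams()


@pytest.fixture
def grid():
    """Standard 20 ms simulation grid at 10 us."""
    return TimeGrid(0.0, 0.02, 1e-5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
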