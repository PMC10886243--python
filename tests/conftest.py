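import numpy as np
import pytest

from mcqq.biophysics import AcquisitionParams, PhysioConstants, simulate_signal
from mcqq.phantom import PhantomConfig, make_phantom

# bounds spanning the full phantom statistic ranges, used by fit experiments
WIDE_BOUNDS = {
    "S0": (1.04, 2.12),
    "R2": (7.3, 161.1),
    "Y": (0.0, 1.0),
    "v": (0.003, 0.072),
    "chi_n": (-957.2, 159.7),
}


@pytest.fixture(scope="session")
def consts():
    return PhysioConstants()


@pytest.fixture(scope="session")
def acq24():
    return AcquisitionParams(grid_shape=(24, 24, 24))


@pytest.fixture(scope="session")
def phantom24():
    """(truth, lesion, contra) on a 24^3 grid, seed 3."""
    return make_phantom(PhantomConfig(grid_shape=(24, 24, 24), seed=3))


@pytest.fixture(scope="session")
def signal24(phantom24, acq24, consts):
    return simulate_signal(phantom24[0], acq24, consts)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
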