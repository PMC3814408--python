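import numpy as np
import pytest

from bspctl import LQRConfig, PKParams, discretize
from bspctl.simulate import REFERENCE_RAT


@pytest.fixture(scope="session")
def params():
    return REFERENCE_RAT


@pytest.fixture(scope="session")
def dyn(params):
    return discretize(params)


@pytest.fixture(scope="session")
def lqr_cfg():
    return LQRConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stable_dynamics(rng):
    """Random two-compartment model (hence stable, nonnegative, controllable
    discretization) for randomized linear-algebra checks."""
    k10, k12, k21 = np.exp(rng.uniform(np.log(0.05), np.log(3.0), 3))
    b_in = np.exp(rng.uniform(np.log(0.2), np.log(5.0)))
    return discretize(PKParams(k10=k10, k12=k12, k21=k21, b_in=b_in))
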