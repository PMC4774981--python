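import numpy as np
import pytest

from gliosim.config import (ChemConstants, FluidConstants, LatticeSpec,
                            NetworkGenParams, RemodellingParams)
from gliosim.haemodynamics import blood_viscosity


@pytest.fixture
def fluid():
    return FluidConstants()


@pytest.fixture
def chem():
    return ChemConstants()


@pytest.fixture
def remodel():
    return RemodellingParams()


@pytest.fixture
def genparams():
    return NetworkGenParams()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def set_viscosities(net, fluid):
    for s in net.segments:
        s.mu = blood_viscosity(2 * s.R, s.H, fluid.plasma_viscosity)
    return net


@pytest.fixture
def small_lattice():
    return LatticeSpec(11, 11, 11, 10.0)
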