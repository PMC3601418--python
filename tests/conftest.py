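import numpy as np
import pytest

import climfate as cf


@pytest.fixture(scope="session")
def world():
    return cf.default_world(4)


@pytest.fixture(scope="session")
def emissions(world):
    return cf.build_emission_map(world)


@pytest.fixture(scope="session")
def pcb(world):
    return cf.pcb153()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 3x3 chemical grid for fast scenario tests."""
    return cf.make_chemspace_grid(6.0, 12.0, -5.0, -1.0, step=2.0)


@pytest.fixture(scope="session")
def traits():
    return cf.ThermalTraits()


@pytest.fixture(scope="session")
def bioparams():
    return cf.BioenergeticParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
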