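import numpy as np
import pytest

from unwindfes.cvs import SegmentLibrary
from unwindfes.fixtures import make_two_chain_fixture
from unwindfes.geometry import build_extended_chain, build_ideal_helix


@pytest.fixture(scope="session")
def alpha_library():
    return SegmentLibrary.alpha()

@pytest.fixture(scope="session")
def antibeta_library():
    return SegmentLibrary.antibeta()

@pytest.fixture(scope="session")
def ideal_helix_12():
    return build_ideal_helix(12)

@pytest.fixture(scope="session")
def extended_12():
    return build_extended_chain(12)

@pytest.fixture(scope="session")
def bonded_fixture():
    return make_two_chain_fixture(hbond_distance=2.8, hbond_angle=10.0)

@pytest.fixture(scope="session")
def unbonded_fixture():
    return make_two_chain_fixture(hbond_distance=3.5, hbond_angle=10.0)

@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
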