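import numpy as np
import pytest

from sahc.biomechanics import BodyLandmarks, CentrifugeConfig
from sahc.records import PhaseBoundaries


@pytest.fixture(scope="session")
def body():
    return BodyLandmarks.reference()


@pytest.fixture(scope="session")
def phases():
    return PhaseBoundaries()


@pytest.fixture
def p1(body):
    return CentrifugeConfig.for_position("P1", body, 2.4)


@pytest.fixture
def p2(body):
    return CentrifugeConfig.for_position("P2", body, 2.4)


@pytest.fixture
def p3(body):
    return CentrifugeConfig.for_position("P3", body, 2.4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
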