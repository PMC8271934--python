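import numpy as np
import pytest

from megloc.forward import SphereModel, helmet_array
from megloc.simulate import build_source_space


@pytest.fixture(scope="session")
def sphere():
    return SphereModel(center=np.zeros(3), radius=0.09)


@pytest.fixture(scope="session")
def sensors(sphere):
    """Full-size 306-channel synthetic helmet."""
    return helmet_array(306, sphere)


@pytest.fixture(scope="session")
def toy_sensors(sphere):
    """Small helmet for fast unit tests."""
    return helmet_array(32, sphere)


@pytest.fixture(scope="session")
def toy_space(sphere):
    return build_source_space(sphere, 300)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
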