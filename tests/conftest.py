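import numpy as np
import pytest

from shapepolar.geometry import make_shape
from shapepolar.model import ParameterSet
from shapepolar.stimulus import StimulusProtocol


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def standard_protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def small_circle():
    """Coarse 30 μm circle for fast solver tests."""
    return make_shape("circle", 30, 30, 34)


@pytest.fixture(scope="session")
def small_teardrop():
    return make_shape("teardrop", 30, 20, 34)


@pytest.fixture(scope="session")
def basal_levels():
    """Standard uniform initial concentrations in canonical species order."""
    return np.array([1.0, 1.4, 3.0, 4.5, 1.25, 1.85, 55.0, 30.0, 0.05])
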