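import numpy as np
import pytest

from scalegeom.settheory import (
    PitchClassSet,
    SetClass,
    enumerate_set_classes,
)


@pytest.fixture(scope="session")
def classes_12_5():
    return enumerate_set_classes(12, 5)


@pytest.fixture(scope="session")
def pentatonic_class():
    return SetClass.of(PitchClassSet((0, 2, 4, 7, 9)))


@pytest.fixture(scope="session")
def chromatic_class():
    return SetClass.of(PitchClassSet(tuple(range(12))))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
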