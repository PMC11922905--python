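import numpy as np
import pytest

from psiilight import OpticalConstants
from psiilight.fitting import FitConfig
from psiilight.synth import PROTOCOL_GRID


@pytest.fixture(scope="session")
def consts():
    return OpticalConstants()


@pytest.fixture(scope="session")
def grid():
    return np.asarray(PROTOCOL_GRID)


@pytest.fixture(scope="session")
def fast_config():
    """Factory for a light fitting configuration used in batch tests."""

    def make(model_kind, curve_kind, seed, **kw):
        return FitConfig.fast(model_kind, curve_kind, seed, **kw)

    return make
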