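import numpy as np
import pytest

from giftmap import THEORETIC_PRESETS
from giftmap.encoding import MicrostateVector


@pytest.fixture
def rng():
    return np.random.default_rng(20240816)


@pytest.fixture
def small_vector():
    """Three individuals, one of each microstate, no missing calls."""
    return MicrostateVector("snp_small", np.array([1.0, 0.0, -1.0]))


@pytest.fixture(scope="session")
def presets():
    return THEORETIC_PRESETS
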