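import numpy as np
import pytest

from stochsync.phase_core import KickGain, PRCSpec


@pytest.fixture
def sin_prc():
    return PRCSpec()  # type2 (sin), amplitude 1


@pytest.fixture
def small_gain():
    return KickGain(0.1)


@pytest.fixture
def default_gain():
    return KickGain(0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
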