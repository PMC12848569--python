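import numpy as np
import pytest

from chorusloop import build_stimulus_library

SIM_RATE = 8000  # simulation sample rate: delays/crossfades are integer samples


@pytest.fixture(scope="session")
def library():
    return build_stimulus_library(SIM_RATE)


@pytest.fixture(scope="session")
def library44k():
    return build_stimulus_library(44100)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
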