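import numpy as np
import pytest

from mvlocate import DetectionParams, MovementParams, ReceiverArray, StateSpace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def halfnormal():
    return DetectionParams(family="halfnormal", p0=0.562, sigma_det=0.75)


@pytest.fixture
def move():
    return MovementParams(sigma_u=0.25)


@pytest.fixture
def two_receivers():
    return ReceiverArray(ids=(0, 1), coords=np.array([[0.0, 0.0], [1.0, 0.0]]))


@pytest.fixture
def small_space():
    return StateSpace(-3.0, 4.0, -3.0, 3.0)
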