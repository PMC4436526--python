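import numpy as np
import pytest

from dyadkin import (
    BoardGeometry,
    CrossedCondition,
    Difficulty,
    Feedback,
    synth_actor,
    synth_imitator,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def board():
    return BoardGeometry()


@pytest.fixture(scope="session")
def small_actor(board):
    """A short (2-trial) simple-condition actor session with ground truth."""
    rng = np.random.default_rng(7)
    return synth_actor(board, Difficulty.simple, rng, n_trials=2)


@pytest.fixture(scope="session")
def small_dyad(small_actor):
    """Actor plus a noiseless imitator lagged by 0.3 s."""
    actor, gt = small_actor
    rng = np.random.default_rng(8)
    imitator, igt = synth_imitator(actor, 0.3, 0.0, 1.0, rng)
    return actor, imitator, gt, igt
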