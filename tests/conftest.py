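import numpy as np
import pytest

from wevreg import FitConfig, TrainingSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_train(rng):
    """15 random rows in 4-D with uniform targets, min-max normalized."""
    X = rng.random((15, 4))
    y = rng.random(15)
    return TrainingSet.from_raw(X, y)


@pytest.fixture
def small_cfg():
    return FitConfig(k=5, gamma=0.5, num_epochs=5)


def random_training_set(rng, n=None, q=None):
    n = n or int(rng.integers(3, 20))
    q = q or int(rng.integers(1, 6))
    return TrainingSet.from_raw(rng.random((n, q)), rng.random(n))
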