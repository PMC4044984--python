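import numpy as np
import pytest

from bvroctree import Dataset


@pytest.fixture
def worked_example():
    """Eight classifier outputs with desired labels; the canonical HRL fixture."""
    scores = np.array([-1.0, -0.4, -0.7, -0.9, 0.01, 0.5, 0.9, 1.0])
    labels = np.array([-1, -1, 1, -1, -1, -1, 1, 1])
    return scores, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def random_scored_labels(rng, n, tie_prob=0.3):
    """Scores (with deliberate tie mass) and labels containing both classes."""
    if rng.random() < tie_prob:
        scores = rng.integers(0, max(2, n // 2), size=n).astype(float)
    else:
        scores = rng.standard_normal(n)
    labels = rng.choice([-1, 1], size=n)
    if labels.min() == labels.max():
        labels[rng.integers(n)] *= -1
    return scores, labels


@pytest.fixture
def tiny_dataset(rng):
    """Six samples, three genes, hand-checkable."""
    X = rng.standard_normal((6, 3))
    y = np.array([-1, -1, -1, 1, 1, 1])
    return Dataset(matrix=X, labels=y)
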