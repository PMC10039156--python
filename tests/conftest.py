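import numpy as np
import pytest

from dicepp.data import one_hot_encode


def random_prob_map(rng, shape=(8, 8), n_classes=2, interior=False):
    """A valid random probability map; ``interior`` keeps entries away from
    0/1 so finite-difference gradients are well defined."""
    lo = 0.05 if interior else 0.0
    raw = rng.uniform(lo, 1.0, shape + (n_classes,))
    return raw / raw.sum(axis=-1, keepdims=True)


def random_one_hot(rng, shape=(8, 8), n_classes=2):
    mask = rng.integers(0, n_classes, shape)
    return one_hot_encode(mask, n_classes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_pixel_case():
    """The canonical 4-pixel binary worked example: y_fg = [1,1,0,0],
    p_fg = [1.0, 0.5, 0.5, 0.0], arranged on a 2x2 grid."""
    y_fg = np.array([1.0, 1.0, 0.0, 0.0])
    p_fg = np.array([1.0, 0.5, 0.5, 0.0])
    p = np.stack([1 - p_fg, p_fg], axis=-1).reshape(2, 2, 2)
    y = np.stack([1 - y_fg, y_fg], axis=-1).reshape(2, 2, 2)
    return p, y
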