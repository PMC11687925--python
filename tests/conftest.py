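import numpy as np
import pytest

from kapurseg import GrayHistogram, GrayImage


class ForcedRng:
    """Stand-in random stream returning a fixed value, for hand-arithmetic tests."""

    def __init__(self, value: float = 0.5):
        self.value = value

    def random(self, shape=None):
        if shape is None:
            return self.value
        return np.full(shape, self.value)


@pytest.fixture
def forced_rng():
    return ForcedRng


@pytest.fixture
def uniform_hist_64():
    return GrayHistogram(counts=np.ones(64, dtype=int), levels=64)


@pytest.fixture
def bimodal_hist_64():
    """Smooth two-peak 64-level histogram (deterministic closed-form counts)."""
    levels = np.arange(64)
    counts = (
        np.exp(-0.5 * ((levels - 18) / 5.0) ** 2) * 4000
        + np.exp(-0.5 * ((levels - 45) / 6.0) ** 2) * 5000
    ).astype(int) + 1
    return GrayHistogram(counts=counts, levels=64)


@pytest.fixture
def small_image_8bit():
    rng = np.random.default_rng(123)
    return GrayImage(pixels=rng.integers(0, 256, size=(32, 32)), bit_depth=8)
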