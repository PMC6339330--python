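import numpy as np
import pytest

from mrdenoise.image import Image2D


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    return Image2D(rng.uniform(0.0, 1.0, size=(16, 16)), 1.0)


@pytest.fixture
def constant_image():
    return Image2D(np.full((12, 12), 0.4), 1.0)


def make_image(rng, shape=(16, 16), max_intensity=1.0):
    return Image2D(rng.uniform(0.0, max_intensity, size=shape), max_intensity)
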