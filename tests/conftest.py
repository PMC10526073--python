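import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gray(rng):
    """A small random grayscale image, float values in [0, 255]."""
    return rng.uniform(0.0, 255.0, size=(32, 32))
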