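import numpy as np
import pytest

from virts.core import TransformConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return TransformConfig()


@pytest.fixture
def small_random_image(rng):
    """16x16 integer gray image, valued 1..255 so windows are rarely flat."""
    return rng.integers(1, 256, size=(16, 16)).astype(float)
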