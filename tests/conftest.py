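import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def image_pair(rng):
    """A 32x32 RGB pair: an image and a noisy variant of it, both in [0,1]."""
    a = rng.random((32, 32, 3))
    b = np.clip(a + rng.normal(0, 0.08, a.shape), 0.0, 1.0)
    return a, b
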