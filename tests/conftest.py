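import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mask_pair(rng):
    """A pair of random non-empty 16x16 binary masks."""

    def make(size=16, density=0.3):
        while True:
            a = (rng.random((size, size)) < density).astype(np.uint8)
            b = (rng.random((size, size)) < density).astype(np.uint8)
            if a.any() and b.any():
                return a, b

    return make
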