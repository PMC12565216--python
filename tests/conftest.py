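import numpy as np
import pytest

from hfuscad.images import BModeImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return BModeImage(rng.integers(0, 256, (64, 64), dtype=np.uint8).astype(np.uint8))
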