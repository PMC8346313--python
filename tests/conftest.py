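import numpy as np
import pytest

from echoenhance import phantom
from echoenhance.image import EchoImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    return phantom.default_phantom_spec(32, 32)


@pytest.fixture
def clean_image(small_spec):
    return phantom.generate_phantom(small_spec)


@pytest.fixture
def random_image_pair(rng):
    def make(shape=(16, 16), bit_depth=8):
        return (
            EchoImage(rng.random(shape), bit_depth=bit_depth),
            EchoImage(rng.random(shape), bit_depth=bit_depth),
        )

    return make
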