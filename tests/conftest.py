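import numpy as np
import pytest

from refdip import ComplexImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    def make(n=16):
        return ComplexImage(rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)))

    return make
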