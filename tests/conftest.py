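import numpy as np
import pytest

from tcam import make_m_transform


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dct4():
    return make_m_transform(4, "dct2")


@pytest.fixture
def tensor_5x7x4(rng):
    return rng.standard_normal((5, 7, 4))


def random_mdf_tensor(rng, m, p, n):
    a = rng.standard_normal((m, p, n))
    return a - a.mean(axis=0, keepdims=True)
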