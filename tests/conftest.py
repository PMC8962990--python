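import numpy as np
import pytest

from hyperstrip import fig1_se


@pytest.fixture(scope="session")
def se11():
    return fig1_se()


@pytest.fixture(scope="session")
def se11_offsets(se11):
    return [tuple(o) for o in se11.offsets]


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_volume(rng, shape=(9, 9, 5), high=200):
    return rng.integers(0, high, size=shape).astype(np.uint8)
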