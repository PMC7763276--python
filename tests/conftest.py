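import numpy as np
import pytest

from osmoqens.synthetic import make_instrument


@pytest.fixture(scope="session")
def in6():
    """Time-of-flight-like instrument profile used across QENS tests."""
    return make_instrument("in6_like")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
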