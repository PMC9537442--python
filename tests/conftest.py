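import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_surface():
    return np.ones((16, 16))


@pytest.fixture
def random_surface(rng):
    """Small strictly positive lognormal resistance surface."""
    return np.exp(rng.normal(0.0, 1.0, (12, 12)))
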