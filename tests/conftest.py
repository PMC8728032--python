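import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def mvn_sample(rng):
    """A well-behaved 50 x 5 standard-normal sample."""
    return rng.standard_normal((50, 5))


@pytest.fixture
def lognormal_sample(rng):
    """A strongly non-normal 50 x 5 sample (elementwise exp of normals)."""
    return np.exp(rng.standard_normal((50, 5)))
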