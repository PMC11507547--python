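import numpy as np
import pytest

from coitad import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_symmetric(rng, n, scale=10.0):
    """A random symmetric non-negative matrix."""
    upper = rng.uniform(0, scale, (n, n))
    return np.triu(upper) + np.triu(upper, 1).T


@pytest.fixture
def random_matrix(rng):
    def make(n, resolution_kb=40, scale=10.0):
        return ContactMatrix(random_symmetric(rng, n, scale), resolution_kb=resolution_kb)

    return make
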