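import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, n_min=8, n_max=25, c_min=2, c_max=15):
    """A small random feature/outcome problem."""
    n = int(rng.integers(n_min, n_max))
    c = int(rng.integers(c_min, c_max))
    return rng.standard_normal((n, c)), rng.standard_normal(n)
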