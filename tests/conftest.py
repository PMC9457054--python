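import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_prob_vector(rng, n):
    """Dirichlet draw with strictly positive entries."""
    p = rng.dirichlet(np.ones(n))
    p = np.clip(p, 1e-12, None)
    return p / p.sum()
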