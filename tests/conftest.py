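import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance(rng, n_min=5, n_max=10):
    """Small random labeled feature with at least one case and control."""
    n = int(rng.integers(n_min, n_max + 1))
    n1 = int(rng.integers(1, n))
    values = rng.normal(size=n)
    labels = np.zeros(n, dtype=np.int8)
    labels[rng.choice(n, n1, replace=False)] = 1
    return values, labels
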