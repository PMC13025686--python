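import numpy as np
import pytest

from cigbls.pipeline import WindowedDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_design(rng, n=40, m=6, c=1):
    """Small random supervised design for solver-level tests."""
    X = rng.uniform(0.0, 1.0, size=(n, m))
    Y = rng.standard_normal((n, c))
    return WindowedDesign(X, Y, np.zeros(n, dtype=object),
                          tuple(f"v{i}" for i in range(m)))


@pytest.fixture
def small_design(rng):
    return random_design(rng)
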