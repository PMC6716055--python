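import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def gaussian_grid():
    """Standard-normal density on a symmetric uniform grid (2**12 points)."""
    from levyhrv import GridFunction

    x = np.linspace(-80.0, 80.0, 2**12, endpoint=False)
    x = x + (x[1] - x[0]) / 2.0
    vals = np.exp(-(x**2) / 2.0) / np.sqrt(2.0 * np.pi)
    return GridFunction(x, vals)
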