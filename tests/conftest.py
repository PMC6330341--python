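import numpy as np
import pytest

from immunoarch.core_io import PointPattern, rectangle_window


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def window_500():
    return rectangle_window(0.0, 0.0, 500.0, 500.0)


@pytest.fixture
def csr_pattern(rng, window_500):
    """Homogeneous binomial pattern with 100 points in a 0.5 mm window."""
    pts = np.column_stack([rng.uniform(0, 500, 100), rng.uniform(0, 500, 100)])
    return PointPattern(pts, window_500)
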