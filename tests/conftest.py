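import numpy as np
import pytest

from mfscreen.scales import ScaleGrid


@pytest.fixture
def small_grid():
    """Compact 2D ladder for transform-level tests (unit_scale 1 px)."""
    return ScaleGrid.geometric(2.0, 8.0, 10, unit_scale=1.0, fit_range=(2.0, 8.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def gaussian_bump(n: int, sigma: float, center=None) -> np.ndarray:
    c = (n - 1) / 2 if center is None else center
    y, x = np.indices((n, n))
    if np.isscalar(c):
        cy = cx = c
    else:
        cy, cx = c
    return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
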