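import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from morphograd import ModelParameters
from morphograd.validation import regime_grid

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def grid():
    """Parameter sets spanning all qualitative regimes of the model."""
    return regime_grid()


@pytest.fixture(scope="session")
def grid_full_zone(grid):
    """Regime-grid cells with w == L0 (the whole tissue initially transcribes)."""
    return [p for p in grid if p.w == p.L0]


def dense_argmin(params: ModelParameters, t: float, n: int = 100_000):
    """Brute-force location of the concentration minimum over the exterior.

    Returns (position of grid argmin, grid spacing)."""
    from morphograd import analytic, tissue_length

    L = float(tissue_length(params, t))
    x = np.linspace(params.w, L, n)
    c = analytic.concentration(params, x, t)
    return float(x[np.argmin(c)]), float(x[1] - x[0])


def second_diff_sign_change(params: ModelParameters, t: float, n: int = 100_000):
    """First +to- sign change of the second finite difference on a dense
    exterior grid, or None; returns (position, grid spacing)."""
    from morphograd import analytic, tissue_length

    L = float(tissue_length(params, t))
    x = np.linspace(params.w, L, n)
    c = analytic.concentration(params, x, t)
    d2 = np.diff(c, 2)
    # band just above the ~eps*c rounding floor of a second difference
    band = 16 * np.finfo(float).eps * np.max(np.abs(c))
    sign = np.where(d2 > band, 1, np.where(d2 < -band, -1, 0))
    nz = np.flatnonzero(sign)
    h = float(x[1] - x[0])
    for i, j in zip(nz[:-1], nz[1:]):
        if sign[i] > 0 and sign[j] < 0:
            # linear interpolation of d2 across the crossing
            xa, xb = x[i + 1], x[j + 1]
            x0 = xa + (xb - xa) * d2[i] / (d2[i] - d2[j])
            return float(x0), h
    return None, h
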