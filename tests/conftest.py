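import numpy as np
import pytest

from cortifield.dynamics import KGParams, LimitCycleParams, QuarticParams
from cortifield.grid_fields import FieldState, GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def grid16():
    return GridSpec(16, 16, dx=1.0, dy=1.0, boundary="periodic")


@pytest.fixture
def grid32():
    return GridSpec(32, 32, dx=1.0, dy=1.0, boundary="periodic")


@pytest.fixture
def random_state(grid16, rng):
    phi = rng.standard_normal(grid16.shape) + 1j * rng.standard_normal(grid16.shape)
    phi_dot = rng.standard_normal(grid16.shape) + 1j * rng.standard_normal(grid16.shape)
    return FieldState(grid16, phi, phi_dot, t=0.0)


@pytest.fixture
def kg_params():
    return KGParams(c=1.0, m=0.5)


@pytest.fixture
def quartic_params():
    return QuarticParams(c0=1.0, a2=1.0, a3=0.5)


@pytest.fixture
def lc_params():
    return LimitCycleParams(c1=1.0, c2=-1.0, c3=1.0)


def commensurate_k(grid, nx_waves=2, ny_waves=0):
    """Exact lattice wavevector with the given integer wave counts."""
    return (
        2 * np.pi * nx_waves / (grid.nx * grid.dx),
        2 * np.pi * ny_waves / (grid.ny * grid.dy),
    )
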