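import numpy as np
import pytest

from patjrec.grid import make_grid, place_sensors


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_grid():
    """32^2-interior grid with sensor and PML bands (full 64^2)."""
    return make_grid(32, 2e-4, 4, 12, 4e-8, 64)


@pytest.fixture
def small_sensors(small_grid):
    return place_sensors(small_grid, 24, 4e-4)


@pytest.fixture
def heterogeneous_c(small_grid, rng):
    c = 1500.0 + 80.0 * rng.standard_normal((small_grid.n_total,) * 2)
    return np.clip(c, 1350.0, 1650.0)
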