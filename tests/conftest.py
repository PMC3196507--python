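import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cadsort as cs

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_state(grid, levels, target_volume=None):
    """Build a LatticeState from an integer grid and per-cell level list.

    ``levels`` indexes cells 1..n; target volumes default to each cell's
    actual pixel count (zero volume stress).
    """
    grid = np.asarray(grid, dtype=np.int32)
    n = int(grid.max())
    lev = np.zeros(n + 1)
    lev[1:] = levels
    counts = np.bincount(grid.ravel(), minlength=n + 1)
    tv = np.asarray(counts, dtype=np.int64).copy()
    if target_volume is not None:
        tv[1:] = target_volume
    tv[0] = 0
    return cs.LatticeState(grid=grid, levels=lev, target_volumes=tv)


def random_two_cell_state(rng, size=12, n_cells=2, levels=None):
    """A seeded random blob state: cells occupy random pixels of the interior."""
    grid = np.zeros((size, size), dtype=np.int32)
    interior = [(r, c) for r in range(2, size - 2) for c in range(2, size - 2)]
    picks = rng.choice(len(interior), size=len(interior) // 2, replace=False)
    for j, k in enumerate(picks):
        r, c = interior[k]
        grid[r, c] = (j % n_cells) + 1  # every cell gets pixels
    if levels is None:
        levels = rng.uniform(1, 23, n_cells)
    return make_state(grid, levels, target_volume=10)


@pytest.fixture
def thbm():
    return cs.BindingModel("THBM", k_eff=1.0, delta_G=-1.0, J0=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
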