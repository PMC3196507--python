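"""Initial-condition builder: circular-disk aggregates with assigned levels.

An aggregate starts as a circular disk of area ~ n_cells * target_volume
pixels, partitioned into connected, near-equal-volume cells, centered on a
lattice with enough margin that the aggregate never reaches the border.
Cadherin expression numbers are then assigned i.i.d. — uniformly over a
discrete level list, or uniformly over a continuous range — with every
allowed number having equal probability.

The partition is built by k-means on the disk's pixel coordinates (nearest-
centroid assignment gives convex, connected cells) followed by a short
relaxation at homogeneous adhesion, which equilibrates cell shapes and
volumes before the levels are drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.spatial import cKDTree

from .binding import BindingKind, BindingModel
from .lattice import LatticeState, SimulationConfig


@dataclass(frozen=True)
class LevelScheme:
    """A cadherin expression assignment rule.

    Discrete mode draws uniformly from ``levels`` (>= 2 distinct positive
    values, ascending); continuous mode draws uniformly from ``range``.
    """

    mode: str  # "discrete" | "continuous"
    levels: tuple[float, ...] | None = None
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode == "discrete":
            if self.levels is None or len(self.levels) < 2:
                raise ValueError("discrete scheme needs >= 2 levels")
            lv = tuple(float(x) for x in self.levels)
            if any(x <= 0 for x in lv) or list(lv) != sorted(set(lv)):
                raise ValueError("levels must be distinct positive ascending")
            object.__setattr__(self, "levels", lv)
        elif self.mode == "continuous":
            if self.range is None:
                raise ValueError("continuous scheme needs a range")
            lo, hi = self.range
            if not (0 < lo < hi):
                raise ValueError("continuous range needs 0 < n_min < n_max")
            object.__setattr__(self, "range", (float(lo), float(hi)))
        else:
            raise ValueError(f"unknown scheme mode {self.mode!r}")

    @property
    def span(self) -> tuple[float, float]:
        if self.mode == "discrete":
            return self.levels[0], self.levels[-1]
        return self.range

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "discrete":
            return rng.choice(np.asarray(self.levels), size=n)
        return rng.uniform(self.range[0], self.range[1], size=n)

    @staticmethod
    def discrete(levels: Sequence[float]) -> "LevelScheme":
        return LevelScheme(mode="discrete", levels=tuple(levels))

    @staticmethod
    def continuous(n_min: float, n_max: float) -> "LevelScheme":
        return LevelScheme(mode="continuous", range=(n_min, n_max))


# The schemes and two-level ranges of the published sorting studies: two,
# three, five and nine evenly spaced levels on [1, 23], a continuous uniform
# scheme on the same span, and seven two-level range variants.
_CATALOG: dict[str, LevelScheme] = {
    "levels2": LevelScheme.discrete([1, 23]),
    "levels3": LevelScheme.discrete([1, 12, 23]),
    "levels5": LevelScheme.discrete([1, 6.5, 12, 17.5, 23]),
    "levels9": LevelScheme.discrete(
        [1, 3.75, 6.5, 10.25, 12, 14.75, 17.5, 20.25, 23]
    ),
    "continuous": LevelScheme.continuous(1, 23),
    "range-1-12": LevelScheme.discrete([1, 12]),
    "range-1-14.75": LevelScheme.discrete([1, 14.75]),
    "range-1-17.5": LevelScheme.discrete([1, 17.5]),
    "range-1-20.25": LevelScheme.discrete([1, 20.25]),
    "range-1-23": LevelScheme.discrete([1, 23]),
    "range-12-23": LevelScheme.discrete([12, 23]),
    "range-19.62-23": LevelScheme.discrete([19.62, 23]),
}


def reference_level_schemes() -> dict[str, LevelScheme]:
    """Catalog of the standard level schemes, addressable by name."""
    return dict(_CATALOG)


def get_scheme(name: str) -> LevelScheme:
    try:
        return _CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; available: {sorted(_CATALOG)}"
        ) from None


def build_circular_aggregate(
    n_cells: int,
    target_volume: int,
    scheme: LevelScheme,
    seed: int,
    margin: int = 10,
    relax_mcs: int = 50,
    relax_config: SimulationConfig | None = None,
    lattice_size: int | None = None,
) -> LatticeState:
    """Construct the initial disk aggregate.

    Parameters
    ----------
    n_cells, target_volume
        Number of cells and per-cell target volume in pixels; the disk has
        area ~ ``n_cells * target_volume``.
    scheme
        Level assignment rule (see :class:`LevelScheme`).
    seed
        Controls partition seeding, relaxation and level draws; runs are
        deterministic given the seed.
    margin
        Minimum free border around the disk, in pixels.
    relax_mcs
        Short homogeneous-adhesion relaxation before levels are assigned,
        removing partition artifacts from cell shapes.
    lattice_size
        Override the default square lattice side.

    Raises
    ------
    ValueError
        If an explicit ``lattice_size`` cannot hold the disk plus margin.
    """
    if n_cells < 1 or target_volume < 1:
        raise ValueError("n_cells and target_volume must be >= 1")
    area = n_cells * target_volume
    radius = math.sqrt(area / math.pi)
    min_side = 2 * (math.ceil(radius) + margin)
    side = lattice_size if lattice_size is not None else min_side
    if side < min_side:
        raise ValueError(
            f"lattice size {side} too small for disk radius {radius:.1f} + margin {margin}"
        )
    rng = np.random.default_rng(seed)
    cy = cx = side / 2.0
    rr, cc = np.mgrid[0:side, 0:side]
    disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
    pts = np.column_stack(np.nonzero(disk)).astype(float)

    grid = np.zeros((side, side), dtype=np.int32)
    if n_cells == 1:
        # carve the target_volume pixels nearest the center
        d2 = (pts[:, 0] - cy) ** 2 + (pts[:, 1] - cx) ** 2
        keep = pts[np.argsort(d2)[:target_volume]].astype(int)
        grid[keep[:, 0], keep[:, 1]] = 1
    else:
        _, labels = kmeans2(pts, n_cells, minit="++", seed=rng, iter=20)
        # nearest-centroid reassignment guarantees convex (connected) cells
        cents = np.array(
            [pts[labels == i].mean(axis=0) for i in range(n_cells)]
        )
        _, labels = cKDTree(cents).query(pts)
        grid[pts[:, 0].astype(int), pts[:, 1].astype(int)] = labels.astype(np.int32) + 1

    levels = np.zeros(n_cells + 1)
    levels[1:] = 1.0  # homogeneous placeholder during relaxation
    tv = np.full(n_cells + 1, target_volume, dtype=np.int64)
    tv[0] = 0
    state = LatticeState(grid=grid, levels=levels, target_volumes=tv)

    if relax_mcs > 0:
        from .dynamics import monte_carlo_step

        base = relax_config or SimulationConfig(seed=seed)
        # moderate homotypic interface energy keeps cells intact while shapes
        # equilibrate; a stiff volume constraint during relaxation stops the
        # aggregate's surface tension from compressing cells below target
        cfg = SimulationConfig(
            motility_T=base.motility_T,
            lambda_vol=40.0,
            J_cell_medium=base.J_cell_medium,
            adhesion_neighbor_order=base.adhesion_neighbor_order,
            copy_neighbor_order=base.copy_neighbor_order,
            mcs_budget=relax_mcs,
            seed=seed,
        )
        relax_model = BindingModel(kind=BindingKind.THBM, k_eff=1.0, delta_G=-1.0, J0=7.0)
        monte_carlo_step(state, relax_model, cfg, n_mcs=relax_mcs, seed=seed)
        _reabsorb_fragments(state)

    state.levels[1:] = scheme.draw(n_cells, rng)
    return state


def _reabsorb_fragments(state: LatticeState) -> None:
    """Reassign all but each cell's largest 4-connected component.

    Long-range pixel copies transiently detach single pixels from their
    cells; the initial condition is defined to have connected cells, so
    stray fragments are handed to the majority unit-distance neighbor cell
    (or medium) and volumes recounted.
    """
    from scipy.ndimage import label

    grid = state.grid
    h, w = grid.shape
    for i in range(1, state.n_cells + 1):
        mask = grid == i
        lab, ncomp = label(mask)
        if ncomp <= 1:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        for comp in range(1, ncomp + 1):
            if comp == keep:
                continue
            for r, c in zip(*np.nonzero(lab == comp)):
                votes: dict[int, int] = {}
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and grid[rr, cc] != i:
                        votes[int(grid[rr, cc])] = votes.get(int(grid[rr, cc]), 0) + 1
                grid[r, c] = max(votes, key=votes.get) if votes else 0
    state.volumes = state.recount_volumes()
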