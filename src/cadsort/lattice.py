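"""Lattice state and effective energy for the Glazier-Graner-Hogeweg model.

Cells are extended domains of pixels on a 2D square lattice sharing a cell
index; index 0 is the cell-culture medium.  The effective energy is

    H = sum_links J(sigma_i, sigma_j) + sum_cells lambda_vol * (V - V_t)^2

where the adhesion sum runs over unordered pairs of lattice sites up to
fourth-nearest neighbors that belong to different cells, J is the contact
energy (from the binding model for cell-cell pairs, a constant for
cell-medium pairs), and the second term is an elastic volume constraint.
Boundary conditions are fixed (non-periodic); lattices are sized so
aggregates never reach the border.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binding import BindingModel

# Square-lattice neighbor shells by Euclidean distance:
# order 1: d=1 (4 sites), order 2: d=sqrt(2) (4), order 3: d=2 (4),
# order 4: d=sqrt(5) (8).  The order-<=4 neighborhood has 20 sites.
_SHELLS: dict[int, list[tuple[int, int]]] = {
    1: [(1, 0), (-1, 0), (0, 1), (0, -1)],
    2: [(1, 1), (1, -1), (-1, 1), (-1, -1)],
    3: [(2, 0), (-2, 0), (0, 2), (0, -2)],
    4: [(2, 1), (2, -1), (-2, 1), (-2, -1), (1, 2), (1, -2), (-1, 2), (-1, -2)],
}


def neighborhood_offsets(order: int) -> np.ndarray:
    """All (dr, dc) offsets of the order-``order`` neighborhood (shells 1..order)."""
    if order not in (1, 2, 3, 4):
        raise ValueError(f"neighbor order must be 1..4, got {order}")
    offs = [o for k in range(1, order + 1) for o in _SHELLS[k]]
    return np.asarray(offs, dtype=np.int64)


def half_neighborhood_offsets(order: int) -> np.ndarray:
    """One offset per unordered site pair (the lexicographically positive half)."""
    offs = neighborhood_offsets(order)
    keep = (offs[:, 0] > 0) | ((offs[:, 0] == 0) & (offs[:, 1] > 0))
    return offs[keep]


@dataclass
class SimulationConfig:
    """Parameters of a GGH run.

    ``motility_T`` is the intrinsic cell motility (the temperature-like
    amplitude of membrane fluctuations), ``lambda_vol`` the volume
    elasticity, ``J_cell_medium`` the constant cell-medium contact energy.
    Adhesion and copy neighborhoods default to order 4 (20 sites).
    """

    motility_T: float = 20.0
    lambda_vol: float = 5.0
    J_cell_medium: float = 20.0
    adhesion_neighbor_order: int = 4
    copy_neighbor_order: int = 4
    mcs_budget: int = 30_000
    seed: int = 0
    record_every: int = 200

    def __post_init__(self) -> None:
        if self.motility_T <= 0 or self.lambda_vol <= 0:
            raise ValueError("motility_T and lambda_vol must be positive")
        if self.mcs_budget < 0:
            raise ValueError("mcs_budget must be nonnegative")


@dataclass
class LatticeState:
    """The evolving lattice configuration plus per-cell bookkeeping.

    ``grid`` holds cell indices (0 = medium).  ``levels[i]`` is the cadherin
    expression number of cell ``i`` (entry 0 is unused), ``target_volumes[i]``
    its target volume in pixels, and ``volumes`` is maintained incrementally
    and must always match a full recount of grid occupancies.
    """

    grid: np.ndarray
    levels: np.ndarray
    target_volumes: np.ndarray
    volumes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid = np.ascontiguousarray(self.grid, dtype=np.int32)
        self.levels = np.asarray(self.levels, dtype=np.float64)
        self.target_volumes = np.asarray(self.target_volumes, dtype=np.int64)
        if self.volumes is None:
            self.volumes = self.recount_volumes()
        else:
            self.volumes = np.asarray(self.volumes, dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def n_cells(self) -> int:
        return len(self.levels) - 1

    def recount_volumes(self) -> np.ndarray:
        return np.bincount(self.grid.ravel(), minlength=len(self.levels)).astype(
            np.int64
        )

    def check_consistent(self) -> None:
        """Raise if the incremental volume bookkeeping has drifted."""
        recount = self.recount_volumes()
        if not np.array_equal(recount, self.volumes):
            raise RuntimeError("volume bookkeeping inconsistent with grid occupancy")
        present = np.unique(self.grid)
        if present.max(initial=0) >= len(self.levels):
            raise RuntimeError("grid contains a cell index with no cell entry")

    def copy(self) -> "LatticeState":
        return LatticeState(
            grid=self.grid.copy(),
            levels=self.levels.copy(),
            target_volumes=self.target_volumes.copy(),
            volumes=self.volumes.copy(),
        )

    # -- snapshot I/O --------------------------------------------------------
    def save_labels(self, path: str | Path) -> None:
        """Write the label map as whitespace-separated integers, one row per line."""
        np.savetxt(path, self.grid, fmt="%d")

    def save(self, path: str | Path) -> None:
        """Write label map plus per-cell table (level, target volume) as text."""
        path = Path(path)
        with path.open("w") as fh:
            h, w = self.grid.shape
            fh.write(f"# cadsort lattice snapshot {h} {w} {self.n_cells}\n")
            fh.write("# scale: 2 microns/pixel (metadata only)\n")
            for i in range(1, self.n_cells + 1):
                fh.write(
                    f"# cell {i} level {float(self.levels[i])!r} "
                    f"target {int(self.target_volumes[i])}\n"
                )
            np.savetxt(fh, self.grid, fmt="%d")

    @classmethod
    def load(cls, path: str | Path) -> "LatticeState":
        path = Path(path)
        levels: dict[int, float] = {}
        targets: dict[int, int] = {}
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                parts = line.split()
                if len(parts) >= 6 and parts[1] == "cell":
                    levels[int(parts[2])] = float(parts[4])
                    targets[int(parts[2])] = int(parts[6]) if len(parts) > 6 else int(parts[5])
        grid = np.loadtxt(path, dtype=np.int32, comments="#")
        n = int(grid.max())
        lev = np.zeros(n + 1)
        tv = np.zeros(n + 1, dtype=np.int64)
        for i in range(1, n + 1):
            lev[i] = levels.get(i, 1.0)
            tv[i] = targets.get(i, 0)
        return cls(grid=grid, levels=lev, target_volumes=tv)


def contact_energy(
    state: LatticeState, model: BindingModel, config: SimulationConfig, a: int, b: int
) -> float:
    """Contact energy J between the cells at two sites (0 for same cell)."""
    if a == b:
        return 0.0
    if a == 0 or b == 0:
        return config.J_cell_medium
    return model.contact_energy(state.levels[a], state.levels[b])


def _pair_energy_table(
    state: LatticeState, model: BindingModel, config: SimulationConfig
) -> np.ndarray:
    """Dense (n+1)x(n+1) contact-energy lookup J[a, b]; diagonal zero."""
    from .binding import BindingKind

    lev = state.levels
    n = len(lev)
    J = np.empty((n, n))
    n1 = lev[:, None]
    n2 = lev[None, :]

    if model.kind is BindingKind.CDM:
        B = model.k_eff * (n1 * n2) ** 2
    elif model.kind is BindingKind.THBM:
        B = model.k_eff * n1 * n2
    else:
        B = model.k_eff * np.minimum(n1, n2)
    J[:] = model.J0 + model.delta_G * B
    J[0, :] = config.J_cell_medium
    J[:, 0] = config.J_cell_medium
    np.fill_diagonal(J, 0.0)
    return J


def effective_energy(
    state: LatticeState, model: BindingModel, config: SimulationConfig
) -> float:
    """Full effective energy: adhesion over order-<=k unordered site pairs
    between different cells, plus the elastic volume term.  Deterministic."""
    state.check_consistent()
    grid = state.grid
    J = _pair_energy_table(state, model, config)
    E = 0.0
    h, w = grid.shape
    for dr, dc in half_neighborhood_offsets(config.adhesion_neighbor_order):
        r0a, r1a = max(0, dr), min(h, h + dr)
        c0a, c1a = max(0, dc), min(w, w + dc)
        a = grid[r0a - dr : r1a - dr, c0a - dc : c1a - dc]
        b = grid[r0a:r1a, c0a:c1a]
        E += J[a, b].sum()
    dv = state.volumes[1:] - state.target_volumes[1:]
    E += config.lambda_vol * float(np.dot(dv, dv))
    return float(E)


def delta_H(
    state: LatticeState,
    source_site: tuple[int, int],
    target_site: tuple[int, int],
    model: BindingModel,
    config: SimulationConfig,
) -> float:
    """Exact energy change of copying the index at ``source_site`` onto
    ``target_site``, computed incrementally from the links touching the
    target site and the two volume terms.

    Raises
    ------
    ValueError
        If both sites already hold the same cell index (the attempt is a
        no-op and must be rejected upstream).
    """
    grid = state.grid
    s_src = int(grid[source_site])
    s_tgt = int(grid[target_site])
    if s_src == s_tgt:
        raise ValueError("delta_H undefined: source and target hold the same index")
    h, w = grid.shape
    r, c = target_site
    dE = 0.0
    for dr, dc in neighborhood_offsets(config.adhesion_neighbor_order):
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            nb = int(grid[rr, cc])
            dE += contact_energy(state, model, config, s_src, nb) - contact_energy(
                state, model, config, s_tgt, nb
            )
    lam = config.lambda_vol
    if s_tgt != 0:
        v = state.volumes[s_tgt]
        vt = state.target_volumes[s_tgt]
        dE += lam * (((v - 1 - vt) ** 2) - ((v - vt) ** 2))
    if s_src != 0:
        v = state.volumes[s_src]
        vt = state.target_volumes[s_src]
        dE += lam * (((v + 1 - vt) ** 2) - ((v - vt) ** 2))
    return float(dE)


def acceptance_probability(dH: float, motility_T: float) -> float:
    """Modified-Metropolis acceptance: 1 for dH <= 0, else exp(-dH/T)."""
    if motility_T <= 0:
        raise ValueError("motility_T must be positive")
    if dH <= 0:
        return 1.0
    return float(np.exp(-dH / motility_T))


def apply_copy(
    state: LatticeState, source_site: tuple[int, int], target_site: tuple[int, int]
) -> None:
    """Copy the source index onto the target site, updating volumes in place."""
    s_src = int(state.grid[source_site])
    s_tgt = int(state.grid[target_site])
    state.grid[target_site] = s_src
    state.volumes[s_tgt] -= 1
    state.volumes[s_src] += 1
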