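"""Homotypic cluster identification and coalescence dynamics.

Cells that express the same cadherin level and are in direct contact
(sharing at least one unit-distance lattice link) belong to the same
cluster.  As sorting proceeds, small homotypic clusters coalesce into a few
large ones; the per-level cluster counts decay roughly as a power law of
time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .lattice import LatticeState
from .metrics import PowerLawFit, fit_power_law


@dataclass(frozen=True)
class ClusterRecord:
    """Cluster census of one lattice state.

    ``per_level_counts`` maps level -> number of clusters;
    ``per_level_sizes`` maps level -> sorted cluster sizes in cells
    (sizes at each level sum to the number of cells at that level).
    """

    time: int
    per_level_counts: dict[float, int]
    per_level_sizes: dict[float, list[int]]

    @property
    def total_clusters(self) -> int:
        return sum(self.per_level_counts.values())


def cell_adjacency(state: LatticeState) -> set[tuple[int, int]]:
    """Unordered pairs of distinct cells sharing >= 1 order-1 lattice link."""
    grid = state.grid
    pairs: set[tuple[int, int]] = set()
    for a, b in ((grid[:, :-1], grid[:, 1:]), (grid[:-1, :], grid[1:, :])):
        mask = (a != b) & (a > 0) & (b > 0)
        ua, ub = a[mask], b[mask]
        lo = np.minimum(ua, ub)
        hi = np.maximum(ua, ub)
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def find_clusters(state: LatticeState, time: int = 0) -> ClusterRecord:
    """Connected components of the equal-level cell-contact graph, per level.

    Defined for discrete levels; for continuous assignments bin the levels
    first (see :func:`bin_levels`).
    """
    n = state.n_cells
    lev = state.levels
    pairs = [
        (a, b) for a, b in cell_adjacency(state) if lev[a] == lev[b]
    ]
    if pairs:
        rows = np.array([p[0] for p in pairs])
        cols = np.array([p[1] for p in pairs])
        adj = coo_matrix(
            (np.ones(len(pairs)), (rows - 1, cols - 1)), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    counts: dict[float, int] = {}
    sizes: dict[float, list[int]] = {}
    for level in np.unique(lev[1:]):
        members = np.flatnonzero(lev[1:] == level)
        comp = labels[members]
        _, comp_sizes = np.unique(comp, return_counts=True)
        counts[float(level)] = len(comp_sizes)
        sizes[float(level)] = sorted(comp_sizes.tolist())
    return ClusterRecord(time=time, per_level_counts=counts, per_level_sizes=sizes)


def bin_levels(state: LatticeState, n_bins: int) -> LatticeState:
    """Quantile-bin continuous levels so clustering is well defined.

    Returns a copy whose cell levels are replaced by their bin's median.
    """
    out = state.copy()
    lev = out.levels[1:]
    edges = np.quantile(lev, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, lev, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            lev[sel] = float(np.median(lev[sel]))
    out.levels[1:] = lev
    return out


def cluster_dynamics(
    states: Sequence[LatticeState], times: Sequence[int]
) -> tuple[list[ClusterRecord], dict[float, PowerLawFit]]:
    """Cluster census over a state series plus a power-law fit per level.

    Fits cluster count vs. MCS in log-log space for each level (time 0 is
    shifted to the first positive stamp to keep the log defined).  For runs
    that satisfy the sorting condition, counts trend downward (coalescence)
    and the fitted exponents are negative.
    """
    if len(states) < 3:
        raise ValueError("cluster dynamics needs >= 3 time points")
    if len(states) != len(times):
        raise ValueError("states and times must align")
    records = [find_clusters(s, time=t) for s, t in zip(states, times)]
    levels = sorted(records[0].per_level_counts)
    fits: dict[float, PowerLawFit] = {}
    t = np.asarray(times, dtype=float)
    pos = t[t > 0]
    t_fit = np.where(t > 0, t, pos.min() if pos.size else 1.0)
    for level in levels:
        counts = np.array([r.per_level_counts[level] for r in records], dtype=float)
        fits[level] = fit_power_law(t_fit, counts)
    return records, fits
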