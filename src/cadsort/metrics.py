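"""Sorting observables: boundary lengths, normalized decay, relaxation time.

The heterotypic boundary length (HBL) is the total contact length between
cells with *different* cadherin levels, counted over unit-distance lattice
links (an integer contour length; cell-medium links excluded).  The weighted
heterotypic boundary length (WHBL) multiplies each heterotypic link by the
interfacial tension of its level pair, so it equals the total interfacial
energy stored in heterotypic boundaries; with only two levels it reduces to
tension x HBL.  With continuous levels every cell-cell contact is
heterotypic, so the WHBL is the meaningful sorting metric there.

Decay curves are normalized as (L(t) - L_ref) / (L(0) - L_ref) with L_ref
either the empirical minimum over the run or the theoretical minimum of a
perfectly sorted configuration of concentric rings.  The relaxation time is
the first crossing of 1/e by the smoothed normalized series; the sorting
rate is its inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .binding import BindingModel, interfacial_tension
from .lattice import LatticeState

NOT_REACHED = float("inf")


def _hetero_links(state: LatticeState):
    """Yield (levels_a, levels_b) arrays over heterotypic order-1 links."""
    grid = state.grid
    lev = state.levels
    for a, b in (
        (grid[:, :-1], grid[:, 1:]),
        (grid[:-1, :], grid[1:, :]),
    ):
        mask = (a != b) & (a > 0) & (b > 0)
        la, lb = lev[a[mask]], lev[b[mask]]
        het = la != lb
        yield la[het], lb[het]


def heterotypic_boundary_length(state: LatticeState) -> int:
    """HBL: unit-distance links between cells with different levels, in pixels."""
    return int(sum(len(la) for la, _ in _hetero_links(state)))


def weighted_heterotypic_boundary_length(
    state: LatticeState, model: BindingModel
) -> float:
    """WHBL: sum of interfacial tension over heterotypic unit-distance links."""
    a = -model.delta_G * model.k_eff / 2.0
    total = 0.0
    from .binding import BindingKind

    for la, lb in _hetero_links(state):
        if model.kind is BindingKind.THBM:
            total += float(np.sum(a * (la - lb) ** 2))
        elif model.kind is BindingKind.CDM:
            total += float(np.sum(a * (la**2 - lb**2) ** 2))
        else:
            total += float(np.sum(a * np.abs(la - lb)))
    return total


def theoretical_min_length(
    state: LatticeState, weighted_by: BindingModel | None = None
) -> float:
    """Minimum (W)HBL of the ideal fully sorted configuration.

    Cells of each level form perfect concentric rings ordered by level
    (highest innermost); each internal interface between adjacent level
    groups is a circle of perimeter 2*pi*R_k where R_k = sqrt(A_k/pi) and
    A_k is the cumulative area of the k innermost groups.  With
    ``weighted_by`` given, each interface is multiplied by the interfacial
    tension of its adjacent level pair.
    """
    lev = state.levels[1:]
    vols = state.volumes[1:]
    uniq = np.unique(lev)
    if len(uniq) < 2:
        import warnings

        warnings.warn("theoretical minimum undefined for a single level; returning 0")
        return 0.0
    # descending level order: highest level is the innermost ring
    order = uniq[::-1]
    areas = np.array([vols[lev == u].sum() for u in order], dtype=float)
    cum = np.cumsum(areas)
    total = 0.0
    for k in range(len(order) - 1):
        perim = 2.0 * math.pi * math.sqrt(cum[k] / math.pi)
        if weighted_by is not None:
            perim *= interfacial_tension(weighted_by, order[k], order[k + 1])
        total += perim
    return total


def normalize_series(raw: np.ndarray, reference: float) -> np.ndarray:
    """(L(t) - reference) / (L(0) - reference); equals 1 at t=0."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty series")
    denom = raw[0] - reference
    if denom <= 0:
        raise ValueError(
            f"degenerate normalization: L(0)={raw[0]} must exceed reference={reference}"
        )
    return (raw - reference) / denom


def relaxation_time(
    times: np.ndarray,
    normalized: np.ndarray,
    smooth_window: int = 5,
    interpolate: bool = False,
) -> float:
    """First MCS stamp where the smoothed normalized series crosses below 1/e
    and stays below for the rest of the smoothing window.

    With ``interpolate`` the crossing time is refined linearly between the
    two samples bracketing the threshold, removing the quantization of the
    recording cadence from downstream statistics.

    Returns ``NOT_REACHED`` (inf) if the series never settles below 1/e —
    the incomplete-sorting case.
    """
    times = np.asarray(times)
    y = np.asarray(normalized, dtype=float)
    if y.size == 0:
        raise ValueError("empty series")
    if smooth_window > 1 and y.size >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        ypad = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
        y = np.convolve(ypad, kernel, mode="valid")
    thresh = 1.0 / math.e
    below = y < thresh
    half = max(1, smooth_window // 2)
    for i in np.flatnonzero(below):
        if below[i : i + half].all():
            if interpolate and i > 0 and y[i - 1] > y[i]:
                frac = (y[i - 1] - thresh) / (y[i - 1] - y[i])
                return float(times[i - 1] + frac * (times[i] - times[i - 1]))
            return float(times[i])
    return NOT_REACHED


def sorting_rate(tau: float) -> float:
    """Inverse relaxation time; a never-sorting run (tau = inf) has rate 0."""
    if tau <= 0:
        raise ValueError("relaxation time must be positive")
    if math.isinf(tau):
        return 0.0
    return 1.0 / tau


@dataclass(frozen=True)
class PowerLawFit:
    """y = amplitude * x**exponent, fitted by least squares in log-log space."""

    amplitude: float
    exponent: float
    adjusted_r2: float


def fit_power_law(x: np.ndarray, y: np.ndarray) -> PowerLawFit:
    """Least-squares line fit of log y on log x.

    Requires at least 3 strictly positive points.  The adjusted coefficient
    of determination corrects for the two fitted parameters.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("power-law fit requires strictly positive data")
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    n = x.size
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return PowerLawFit(
        amplitude=float(np.exp(intercept)), exponent=float(slope), adjusted_r2=adj
    )


def cell_centroids(state: LatticeState) -> np.ndarray:
    """(n_cells+1, 2) array of cell centroids in (row, col); row 0 is NaN."""
    grid = state.grid
    n = state.n_cells
    out = np.full((n + 1, 2), np.nan)
    rows, cols = np.nonzero(grid)
    idx = grid[rows, cols]
    counts = np.bincount(idx, minlength=n + 1).astype(float)
    sr = np.bincount(idx, weights=rows, minlength=n + 1)
    sc = np.bincount(idx, weights=cols, minlength=n + 1)
    present = counts > 0
    out[present, 0] = sr[present] / counts[present]
    out[present, 1] = sc[present] / counts[present]
    return out


def radial_sorting_index(state: LatticeState) -> float:
    """Rank correlation between cadherin level and inward radial position.

    Negated Spearman correlation of each cell's level with its centroid's
    distance to the aggregate centroid: +1 means the high expressers sit at
    the center in perfect level order, 0 means no radial ordering, -1 means
    inverted (high expressers outside).
    """
    if state.n_cells < 2:
        raise ValueError("radial sorting index needs at least two cells")
    cent = cell_centroids(state)[1:]
    alive = ~np.isnan(cent[:, 0])
    lev = state.levels[1:][alive]
    if np.unique(lev).size < 2:
        raise ValueError("radial sorting index needs at least two distinct levels")
    pts = cent[alive]
    center = pts.mean(axis=0)
    dist = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    rho = stats.spearmanr(lev, dist).statistic
    return float(-rho)
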