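"""Monte Carlo time evolution: MCS loop, recording, and the simulation driver."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import _run_attempts, _run_scripted
from .binding import BindingModel
from .lattice import (
    LatticeState,
    SimulationConfig,
    _pair_energy_table,
    effective_energy,
    neighborhood_offsets,
)
from .metrics import (
    heterotypic_boundary_length,
    weighted_heterotypic_boundary_length,
)


def monte_carlo_step(
    state: LatticeState,
    model: BindingModel,
    config: SimulationConfig,
    n_mcs: int = 1,
    seed: int | None = None,
) -> int:
    """Advance the lattice by ``n_mcs`` Monte Carlo Steps in place.

    One MCS is W*H displacement attempts on a W x H lattice: pick a random
    site, pick a random site within the copy neighborhood, evaluate the
    incremental energy change and accept with the modified-Metropolis
    probability.  Volume bookkeeping is updated incrementally.  Reproducible
    given the seed (``config.seed`` when ``seed`` is None).

    Returns the number of accepted copies.
    """
    if n_mcs < 0:
        raise ValueError("n_mcs must be nonnegative")
    if n_mcs == 0:
        return 0
    J = _pair_energy_table(state, model, config)
    adh = neighborhood_offsets(config.adhesion_neighbor_order)
    cop = neighborhood_offsets(config.copy_neighbor_order)
    h, w = state.grid.shape
    kseed = int(seed if seed is not None else config.seed) & 0x7FFFFFFF
    return int(
        _run_attempts(
            state.grid,
            J,
            state.volumes,
            state.target_volumes,
            float(config.lambda_vol),
            float(config.motility_T),
            adh,
            cop,
            n_mcs * h * w,
            kseed,
        )
    )


def _scripted_args(state: LatticeState, model: BindingModel, config: SimulationConfig):
    J = _pair_energy_table(state, model, config)
    adh = neighborhood_offsets(config.adhesion_neighbor_order)
    cop = neighborhood_offsets(config.copy_neighbor_order)
    return J, adh, cop


def run_scripted_kernel(
    state: LatticeState,
    model: BindingModel,
    config: SimulationConfig,
    sites: np.ndarray,
    choices: np.ndarray,
    uniforms: np.ndarray,
) -> int:
    """Replay an explicit attempt sequence through the compiled kernel."""
    J, adh, cop = _scripted_args(state, model, config)
    return int(
        _run_scripted(
            state.grid,
            J,
            state.volumes,
            state.target_volumes,
            float(config.lambda_vol),
            float(config.motility_T),
            adh,
            cop,
            np.asarray(sites, dtype=np.int64),
            np.asarray(choices, dtype=np.int64),
            np.asarray(uniforms, dtype=np.float64),
        )
    )


def run_scripted_reference(
    state: LatticeState,
    model: BindingModel,
    config: SimulationConfig,
    sites: np.ndarray,
    choices: np.ndarray,
    uniforms: np.ndarray,
) -> int:
    """Replay an attempt sequence through the pure-Python energy path.

    Uses :func:`cadsort.lattice.delta_H` and the acceptance rule attempt by
    attempt; byte-identical final grids against :func:`run_scripted_kernel`
    certify that the compiled engine computes the same physics as the
    Python oracle.
    """
    from .lattice import acceptance_probability, apply_copy, delta_H

    h, w = state.grid.shape
    cop = neighborhood_offsets(config.copy_neighbor_order)
    accepted = 0
    for p, j, u in zip(sites, choices, uniforms):
        r, c = divmod(int(p), w)
        if r < 2 or r >= h - 2 or c < 2 or c >= w - 2:
            continue
        dr, dc = cop[int(j)]
        src = (r + dr, c + dc)
        if state.grid[src] == state.grid[r, c]:
            continue
        dH = delta_H(state, src, (r, c), model, config)
        if u < acceptance_probability(dH, config.motility_T):
            apply_copy(state, src, (r, c))
            accepted += 1
    return accepted


@dataclass
class RunResult:
    """Time series recorded during a simulation run.

    ``times`` are MCS stamps (starting at 0), ``H`` effective energies,
    ``hbl`` heterotypic boundary lengths (pixels), ``whbl`` tension-weighted
    boundary lengths, ``accepted`` accepted copies per recording interval.
    ``final_state`` is the lattice at the end of the run; ``snapshots`` maps
    MCS stamp -> copied LatticeState when snapshot recording is on.
    """

    times: np.ndarray
    H: np.ndarray
    hbl: np.ndarray
    whbl: np.ndarray
    accepted: np.ndarray
    final_state: LatticeState
    snapshots: dict[int, LatticeState] = field(default_factory=dict)


def simulate(
    state: LatticeState,
    model: BindingModel,
    config: SimulationConfig,
    keep_snapshots_every: int | None = None,
) -> RunResult:
    """Run ``config.mcs_budget`` MCS, recording metrics every
    ``config.record_every`` MCS (including the initial state at t=0).

    The state is evolved in place; the returned result also references it as
    ``final_state``.  Each recording chunk uses a distinct child seed derived
    from ``config.seed``, so runs are reproducible end to end.
    """
    rec = max(1, config.record_every)
    ss = np.random.SeedSequence(config.seed)
    times = [0]
    H = [effective_energy(state, model, config)]
    hbl = [heterotypic_boundary_length(state)]
    whbl = [weighted_heterotypic_boundary_length(state, model)]
    accepted = [0]
    snapshots: dict[int, LatticeState] = {}
    if keep_snapshots_every:
        snapshots[0] = state.copy()
    t = 0
    chunk_seeds = ss.generate_state((config.mcs_budget + rec - 1) // rec or 1)
    i = 0
    while t < config.mcs_budget:
        n = min(rec, config.mcs_budget - t)
        acc = monte_carlo_step(
            state, model, config, n_mcs=n, seed=int(chunk_seeds[i]) & 0x7FFFFFFF
        )
        i += 1
        t += n
        times.append(t)
        H.append(effective_energy(state, model, config))
        hbl.append(heterotypic_boundary_length(state))
        whbl.append(weighted_heterotypic_boundary_length(state, model))
        accepted.append(acc)
        if keep_snapshots_every and t % keep_snapshots_every == 0:
            snapshots[t] = state.copy()
    return RunResult(
        times=np.asarray(times),
        H=np.asarray(H, dtype=float),
        hbl=np.asarray(hbl, dtype=float),
        whbl=np.asarray(whbl, dtype=float),
        accepted=np.asarray(accepted),
        final_state=state,
        snapshots=snapshots,
    )
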