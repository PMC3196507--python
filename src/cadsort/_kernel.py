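"""Numba-compiled inner loop for GGH pixel-copy dynamics.

The energy increment mirrors the pure-Python ``delta_H`` in
:mod:`cadsort.lattice` exactly; the Python version is the correctness
oracle, this one is the engine.  Contact energies are pre-tabulated per
cell pair, the grid is addressed flat with precomputed offsets, and sites
in the outer two-pixel rim are never copy targets (fixed boundary
conditions; lattices carry a >= 10 pixel medium margin, so the rim is
always medium).

``_run_scripted`` executes an externally supplied attempt sequence
(site, neighbor choice, uniform variate) so tests can replay identical
attempts against the Python reference implementation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _attempt_dE(flat, J, volumes, target_volumes, lambda_vol, adh_flat, s_src, s_tgt, p):
    dE = 0.0
    for i in range(adh_flat.shape[0]):
        nb = flat[p + adh_flat[i]]
        dE += J[s_src, nb] - J[s_tgt, nb]
    if s_tgt != 0:
        dv = volumes[s_tgt] - target_volumes[s_tgt]
        dE += lambda_vol * (-2.0 * dv + 1.0)
    if s_src != 0:
        dv = volumes[s_src] - target_volumes[s_src]
        dE += lambda_vol * (2.0 * dv + 1.0)
    return dE


@njit(cache=True)
def _run_attempts(
    grid: np.ndarray,            # (h, w) int32, 0 = medium
    J: np.ndarray,               # (n+1, n+1) float64, J[a, a] = 0
    volumes: np.ndarray,         # (n+1,) int64
    target_volumes: np.ndarray,  # (n+1,) int64
    lambda_vol: float,
    motility_T: float,
    adh_off: np.ndarray,         # (ka, 2) int64 adhesion offsets
    copy_off: np.ndarray,        # (kc, 2) int64 copy offsets
    n_attempts: int,
    seed: int,
) -> int:
    np.random.seed(seed)
    h, w = grid.shape
    flat = grid.ravel()
    adh_flat = adh_off[:, 0] * w + adh_off[:, 1]
    copy_flat = copy_off[:, 0] * w + copy_off[:, 1]
    kc = copy_flat.shape[0]
    n_sites = h * w
    beta = 1.0 / motility_T
    accepted = 0
    for _ in range(n_attempts):
        p = np.random.randint(0, n_sites)
        r = p // w
        c = p - r * w
        if r < 2 or r >= h - 2 or c < 2 or c >= w - 2:
            continue
        q = p + copy_flat[np.random.randint(0, kc)]
        s_tgt = flat[p]
        s_src = flat[q]
        if s_src == s_tgt:
            continue
        dE = _attempt_dE(
            flat, J, volumes, target_volumes, lambda_vol, adh_flat, s_src, s_tgt, p
        )
        if dE <= 0.0 or np.random.random() < math.exp(-dE * beta):
            flat[p] = s_src
            volumes[s_tgt] -= 1
            volumes[s_src] += 1
            accepted += 1
    return accepted


@njit(cache=True)
def _run_scripted(
    grid: np.ndarray,
    J: np.ndarray,
    volumes: np.ndarray,
    target_volumes: np.ndarray,
    lambda_vol: float,
    motility_T: float,
    adh_off: np.ndarray,
    copy_off: np.ndarray,
    sites: np.ndarray,       # (n,) int64 flat target sites
    choices: np.ndarray,     # (n,) int64 copy-neighbor choices
    uniforms: np.ndarray,    # (n,) float64 acceptance variates
) -> int:
    h, w = grid.shape
    flat = grid.ravel()
    adh_flat = adh_off[:, 0] * w + adh_off[:, 1]
    copy_flat = copy_off[:, 0] * w + copy_off[:, 1]
    beta = 1.0 / motility_T
    accepted = 0
    for k in range(sites.shape[0]):
        p = sites[k]
        r = p // w
        c = p - r * w
        if r < 2 or r >= h - 2 or c < 2 or c >= w - 2:
            continue
        q = p + copy_flat[choices[k]]
        s_tgt = flat[p]
        s_src = flat[q]
        if s_src == s_tgt:
            continue
        dE = _attempt_dE(
            flat, J, volumes, target_volumes, lambda_vol, adh_flat, s_src, s_tgt, p
        )
        if dE <= 0.0 or uniforms[k] < math.exp(-dE * beta):
            flat[p] = s_src
            volumes[s_tgt] -= 1
            volumes[s_src] += 1
            accepted += 1
    return accepted
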