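"""Snapshot rendering: gray-scale and HSV level maps, medium in white."""

from __future__ import annotations

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .lattice import LatticeState


def render_snapshot(
    state: LatticeState,
    palette: str = "grayscale",
    level_span: tuple[float, float] | None = None,
) -> Image.Image:
    """Render the lattice with cells colored by cadherin level.

    grayscale: the highest level maps to gray 0 (darkest), the lowest to
    gray 200, medium to 255 (white).  hsv: hue runs linearly from blue
    (lowest level) to red (highest), full saturation and value; medium is
    white.  Deterministic given the state.

    ``level_span`` fixes (n_min, n_max) for consistent coloring across
    frames; defaults to the span present in the state.
    """
    grid = state.grid
    lev = state.levels
    cell_levels = lev[1:][np.flatnonzero(state.volumes[1:] > 0)]
    if level_span is not None:
        n_min, n_max = level_span
    elif cell_levels.size:
        n_min, n_max = float(cell_levels.min()), float(cell_levels.max())
    else:
        n_min, n_max = 0.0, 1.0
    span = n_max - n_min
    frac = np.zeros_like(grid, dtype=float)
    cells = grid > 0
    if span > 0:
        frac[cells] = (lev[grid[cells]] - n_min) / span
    if palette == "grayscale":
        img = np.full(grid.shape, 255, dtype=np.uint8)
        img[cells] = np.round(200.0 * (1.0 - frac[cells])).astype(np.uint8)
        return Image.fromarray(img, mode="L")
    if palette == "hsv":
        hsv = np.zeros(grid.shape + (3,))
        hsv[..., 0] = (2.0 / 3.0) * (1.0 - frac)  # blue (low) -> red (high)
        hsv[..., 1] = np.where(cells, 1.0, 0.0)
        hsv[..., 2] = 1.0
        rgb = (hsv_to_rgb(hsv) * 255).round().astype(np.uint8)
        return Image.fromarray(rgb, mode="RGB")
    raise ValueError(f"unknown palette {palette!r}; use 'grayscale' or 'hsv'")
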