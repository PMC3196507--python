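"""Cadherin binding models: from per-cell expression numbers to adhesion energies.

Three equilibrium binding models relate the cadherin expression numbers of two
apposed cells to the surface density of bound cadherin pairs:

* **CDM** (cis-dimer model): cis-dimers form on each membrane and pairs of
  dimers on apposing cells bind into trans-tetramers, so the bound-pair
  density scales as the *square of the product* of the two expression numbers.
* **THBM** (trans-homophilic-bond model): individual cadherins bind across
  the intercellular gap; bound-pair density scales as the *product*.
* **SM** (saturation model): binding saturates at the lower-expressing cell;
  bound-pair density scales as the *minimum* of the two numbers.

Cells are assumed identical in membrane area, so expression numbers stand in
for surface densities and all geometric factors are folded into the effective
equilibrium constant ``k_eff``.  The cell-cell adhesion energy density is

    e(n1, n2) = J0 + delta_G * B(n1, n2)

with ``delta_G < 0`` the per-bond binding free energy, ``J0`` the baseline
contact energy unrelated to cadherin binding, and ``B`` the bound-pair
density.  The interfacial tension between two cell types is the heterotypic
contact energy minus the mean of the homotypic ones; it is nonnegative for
all three models and drives sorting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence


class BindingKind(str, Enum):
    """Functional form of the bound-pair density."""

    CDM = "CDM"
    THBM = "THBM"
    SM = "SM"


@dataclass(frozen=True)
class BindingModel:
    """A configured cadherin binding model.

    Parameters
    ----------
    kind
        One of :class:`BindingKind` (``CDM``, ``THBM``, ``SM``).
    k_eff
        Effective equilibrium constant (> 0, dimensionless after rescaling).
    delta_G
        Per-bond binding free energy; must be negative (bond formation
        releases energy).
    J0
        Baseline contact energy density unrelated to cadherin binding; may be
        positive (such cells need not cohere).
    """

    kind: BindingKind
    k_eff: float = 1.0
    delta_G: float = -1.0
    J0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_eff <= 0:
            raise ValueError(f"k_eff must be positive, got {self.k_eff}")
        if self.delta_G >= 0:
            raise ValueError(f"delta_G must be negative, got {self.delta_G}")
        if not isinstance(self.kind, BindingKind):
            object.__setattr__(self, "kind", BindingKind(self.kind))

    # -- convenience wrappers -------------------------------------------------
    def bound_pair_density(self, n1: float, n2: float) -> float:
        return bound_pair_density(self, n1, n2)

    def adhesion_energy_density(self, n1: float, n2: float) -> float:
        return adhesion_energy_density(self, n1, n2)

    def interfacial_tension(self, n1: float, n2: float) -> float:
        return interfacial_tension(self, n1, n2)

    def contact_energy(self, n1: float, n2: float) -> float:
        """Alias for the adhesion energy density; the GGH contact energy J."""
        return adhesion_energy_density(self, n1, n2)


def _check_levels(n1: float, n2: float) -> None:
    if not (n1 > 0 and math.isfinite(n1)) or not (n2 > 0 and math.isfinite(n2)):
        raise ValueError(
            f"cadherin expression numbers must be positive and finite, got ({n1}, {n2})"
        )


def bound_pair_density(model: BindingModel, n1: float, n2: float) -> float:
    """Equilibrium density of bound cadherin pairs between two cells.

    Returns ``k_eff*(n1*n2)**2`` (CDM), ``k_eff*n1*n2`` (THBM) or
    ``k_eff*min(n1, n2)`` (SM).
    """
    _check_levels(n1, n2)
    k = model.k_eff
    if model.kind is BindingKind.CDM:
        return k * (n1 * n2) ** 2
    if model.kind is BindingKind.THBM:
        return k * n1 * n2
    return k * min(n1, n2)


def adhesion_energy_density(model: BindingModel, n1: float, n2: float) -> float:
    """Cell-cell adhesion energy density e(n1, n2) = J0 + delta_G * B(n1, n2).

    Strictly decreasing in the bound-pair density since ``delta_G < 0``.
    """
    return model.J0 + model.delta_G * bound_pair_density(model, n1, n2)


def interfacial_tension(model: BindingModel, n1: float, n2: float) -> float:
    """Interfacial tension density between two cell types.

    gamma(n1, n2) = e(n1, n2) - [e(n1, n1) + e(n2, n2)] / 2, evaluated via
    model-specific closed forms (``J0`` cancels):

    * THBM:  (-delta_G * k_eff / 2) * (n1 - n2)**2
    * CDM:   (-delta_G * k_eff / 2) * (n1**2 - n2**2)**2
    * SM:    (-delta_G * k_eff / 2) * |n1 - n2|

    Nonnegative for every valid pair; zero iff ``n1 == n2``.
    """
    _check_levels(n1, n2)
    a = -model.delta_G * model.k_eff / 2.0
    if model.kind is BindingKind.THBM:
        return a * (n1 - n2) ** 2
    if model.kind is BindingKind.CDM:
        return a * (n1 * n1 - n2 * n2) ** 2
    return a * abs(n1 - n2)


@dataclass(frozen=True)
class SortingDiagnostics:
    """Tension bookkeeping behind the two-level wetting/engulfment check.

    ``gamma_12`` is the heterotypic tension, ``gamma_low_medium`` /
    ``gamma_high_medium`` the cell-medium tensions of the lower- and
    higher-expressing type, and ``wetting_margin`` the surplus
    ``gamma_high_medium - gamma_low_medium - gamma_12`` (>= 0 means the
    low-expressing type fully wets the high-expressing one; = 0 is the
    neutral-wetting boundary, reached by the saturation model).
    """

    sorts: bool
    gamma_12: float
    gamma_low_medium: float
    gamma_high_medium: float
    wetting_margin: float


def check_sorting_condition(
    model: BindingModel, n1: float, n2: float, J_cell_medium: float = 20.0
) -> SortingDiagnostics:
    """Decide whether two cell types sort completely (low wets high).

    For complete sorting the less cohesive (lower-expressing) type must wet
    the more cohesive one: the heterotypic tension must be positive and the
    higher-expressing type must have the larger cell-medium tension, with
    ``gamma_high_medium >= gamma_low_medium + gamma_12``.  With a
    level-independent cell-medium contact energy the margin reduces to
    ``delta_G * (B(low, low) - B(low, high)) >= 0``; it is strictly positive
    for CDM and THBM and exactly zero for SM (neutral wetting), so all three
    models satisfy the condition whenever the levels differ.

    Raises
    ------
    ValueError
        If ``n1 == n2`` (the condition is undefined for identical cells).
    """
    _check_levels(n1, n2)
    if n1 == n2:
        raise ValueError("sorting condition undefined for equal expression levels")
    lo, hi = (n1, n2) if n1 < n2 else (n2, n1)
    e = lambda a, b: adhesion_energy_density(model, a, b)  # noqa: E731
    gamma_12 = interfacial_tension(model, lo, hi)
    # medium expresses no cadherin: contact energy with any cell is constant
    gamma_lo_m = J_cell_medium - e(lo, lo) / 2.0
    gamma_hi_m = J_cell_medium - e(hi, hi) / 2.0
    margin = gamma_hi_m - gamma_lo_m - gamma_12
    sorts = gamma_12 > 0 and gamma_hi_m > gamma_lo_m and margin >= -1e-12
    return SortingDiagnostics(
        sorts=sorts,
        gamma_12=gamma_12,
        gamma_low_medium=gamma_lo_m,
        gamma_high_medium=gamma_hi_m,
        wetting_margin=margin,
    )


def match_energy_ranges(
    kinds: Sequence[BindingKind | str],
    level_range: tuple[float, float],
    max_energy_magnitude: float,
    delta_G: float = -1.0,
    J0: float = 0.0,
) -> list[BindingModel]:
    """Configure one model per kind with equal maximum homotypic adhesion.

    Chooses ``k_eff`` for each kind so that the cadherin contribution
    ``|delta_G| * B(n_max, n_max)`` equals ``max_energy_magnitude`` for every
    model, putting the cell-cell adhesion energies in the same range and
    excluding rate differences due purely to energy scale.
    """
    if not kinds:
        raise ValueError("need at least one binding model kind")
    n_min, n_max = level_range
    if not (0 < n_min < n_max):
        raise ValueError(f"need 0 < n_min < n_max, got {level_range}")
    target = max_energy_magnitude / abs(delta_G)
    out: list[BindingModel] = []
    for kind in kinds:
        kind = BindingKind(kind)
        if kind is BindingKind.CDM:
            k = target / (n_max * n_max) ** 2
        elif kind is BindingKind.THBM:
            k = target / (n_max * n_max)
        else:
            k = target / n_max
        out.append(BindingModel(kind=kind, k_eff=k, delta_G=delta_G, J0=J0))
    return out
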