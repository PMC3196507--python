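"""Boundary lengths, normalization, relaxation time, radial sorting index."""

import math

import numpy as np
import pytest

import cadsort as cs
from cadsort.metrics import (
    NOT_REACHED,
    fit_power_law,
    heterotypic_boundary_length,
    normalize_series,
    radial_sorting_index,
    relaxation_time,
    sorting_rate,
    theoretical_min_length,
    weighted_heterotypic_boundary_length,
)

from conftest import make_state, random_two_cell_state


def brute_force_hbl(state):
    """Independent double-loop oracle over unit-distance links."""
    grid, lev = state.grid, state.levels
    h, w = grid.shape
    total = 0
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < h and cc < w:
                    a, b = int(grid[r, c]), int(grid[rr, cc])
                    if a != b and a > 0 and b > 0 and lev[a] != lev[b]:
                        total += 1
    return total


def two_ring_state(size=24, r_in=5.0, r_out=10.0, inner_level=23.0, outer_level=1.0):
    """Perfectly sorted fixture: inner disk cell ringed by an annulus cell."""
    grid = np.zeros((size, size), dtype=np.int32)
    rr, cc = np.mgrid[0:size, 0:size]
    d2 = (rr - size / 2 + 0.5) ** 2 + (cc - size / 2 + 0.5) ** 2
    grid[d2 <= r_out**2] = 2
    grid[d2 <= r_in**2] = 1
    return make_state(grid, [inner_level, outer_level])


class TestBoundaryLengths:
    def test_shared_interface_counted_per_link(self):
        grid = np.zeros((8, 8), dtype=int)
        grid[2:4, 2:4] = 1
        grid[2:4, 4:6] = 2
        st = make_state(grid, [1.0, 23.0])
        assert heterotypic_boundary_length(st) == 2

    def test_homotypic_interface_excluded(self):
        grid = np.zeros((8, 8), dtype=int)
        grid[2:4, 2:4] = 1
        grid[2:4, 4:6] = 2
        st = make_state(grid, [5.0, 5.0])
        assert heterotypic_boundary_length(st) == 0

    def test_sorted_rings_count_inner_interface_only(self):
        st = two_ring_state()
        inner = 0
        grid = st.grid
        for r in range(grid.shape[0]):
            for c in range(grid.shape[1]):
                for dr, dc in ((0, 1), (1, 0)):
                    if r + dr < grid.shape[0] and c + dc < grid.shape[1]:
                        pair = {int(grid[r, c]), int(grid[r + dr, c + dc])}
                        if pair == {1, 2}:
                            inner += 1
        assert heterotypic_boundary_length(st) == inner

    def test_matches_brute_force_on_random_states(self, rng):
        for _ in range(5):
            st = random_two_cell_state(rng, size=12, n_cells=4)
            assert heterotypic_boundary_length(st) == brute_force_hbl(st)

    @pytest.mark.parametrize("kind", ["CDM", "THBM", "SM"])
    def test_whbl_is_tension_times_hbl_for_two_levels(self, kind, rng):
        model = cs.BindingModel(kind, k_eff=0.01, delta_G=-1.0, J0=2.0)
        for _ in range(4):
            st = random_two_cell_state(rng, size=12, n_cells=4, levels=[1, 1, 23, 23])
            gamma = model.interfacial_tension(1, 23)
            assert weighted_heterotypic_boundary_length(st, model) == pytest.approx(
                gamma * heterotypic_boundary_length(st)
            )

    def test_whbl_zero_when_levels_equal(self, thbm, rng):
        st = random_two_cell_state(rng, size=10, n_cells=3, levels=[7, 7, 7])
        assert weighted_heterotypic_boundary_length(st, thbm) == 0.0

    def test_whbl_three_cell_chain_by_hand(self):
        # levels (1, 12, 23), interfaces of 2 links each, SM tension |dn|/2
        grid = np.zeros((8, 8), dtype=int)
        grid[2:4, 1:3] = 1
        grid[2:4, 3:5] = 2
        grid[2:4, 5:7] = 3
        st = make_state(grid, [1.0, 12.0, 23.0])
        sm = cs.BindingModel("SM", k_eff=1.0, delta_G=-1.0)
        assert weighted_heterotypic_boundary_length(st, sm) == pytest.approx(
            2 * (11 / 2) + 2 * (11 / 2)
        )


class TestTheoreticalMinimum:
    def test_two_level_closed_form(self):
        st = two_ring_state(r_in=6.0)
        inner_area = int((st.grid == 1).sum())
        expected = 2 * math.pi * math.sqrt(inner_area / math.pi)
        assert theoretical_min_length(st) == pytest.approx(expected)

    def test_single_level_zero_with_warning(self):
        grid = np.zeros((6, 6), dtype=int)
        grid[2:4, 2:4] = 1
        st = make_state(grid, [5.0])
        with pytest.warns(UserWarning):
            assert theoretical_min_length(st) == 0.0

    def test_three_equal_groups_closed_form(self):
        # three levels, 100 px per group: 2*pi*(sqrt(100/pi) + sqrt(200/pi))
        grid = np.zeros((40, 40), dtype=int)
        grid[0, 0:25] = 1   # geometry is irrelevant; only areas enter
        grid[1, 0:25] = 1
        grid[2, 0:25] = 1
        grid[3, 0:25] = 1
        grid[4:8, 0:25] = 2
        grid[8:12, 0:25] = 3
        st = make_state(grid, [23.0, 12.0, 1.0])
        expected = 2 * math.pi * (math.sqrt(100 / math.pi) + math.sqrt(200 / math.pi))
        assert theoretical_min_length(st) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(85.58, abs=0.01)

    def test_invariant_under_cell_relabeling_within_level(self, rng):
        st = random_two_cell_state(rng, size=14, n_cells=6, levels=[1, 1, 12, 12, 23, 23])
        base = theoretical_min_length(st)
        # swap the two cells at level 12 (indices 3 and 4)
        g = st.grid.copy()
        g[st.grid == 3], g[st.grid == 4] = 4, 3
        swapped = make_state(g, [1, 1, 12, 12, 23, 23])
        assert theoretical_min_length(swapped) == pytest.approx(base)

    def test_weighted_version_scales_interfaces_by_tension(self):
        st = two_ring_state()
        sm = cs.BindingModel("SM", k_eff=1.0, delta_G=-1.0)
        gamma = sm.interfacial_tension(1, 23)
        assert theoretical_min_length(st, weighted_by=sm) == pytest.approx(
            gamma * theoretical_min_length(st)
        )


class TestNormalization:
    def test_endpoints(self):
        out = normalize_series(np.array([100.0, 60.0, 20.0]), 20.0)
        assert out[0] == 1.0
        assert out[1] == pytest.approx(0.5)
        assert out[2] == 0.0

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_series(np.array([10.0, 5.0]), 10.0)


class TestRelaxationTime:
    def test_flat_series_never_relaxes(self):
        t = np.arange(0, 10_000, 100)
        assert relaxation_time(t, np.ones_like(t, dtype=float)) == NOT_REACHED

    def test_exponential_crossing_near_time_constant(self):
        t = np.arange(0, 30_000, 100)
        y = np.exp(-t / 5000.0)
        tau = relaxation_time(t, y)
        assert abs(tau - 5000.0) <= 100.0

    def test_step_series_crossing(self):
        t = np.arange(0, 6000, 1000)
        y = np.where(t < 3000, 1.0, 0.2)
        assert relaxation_time(t, y, smooth_window=1) == 3000.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            relaxation_time(np.array([]), np.array([]))


class TestSortingRate:
    @pytest.mark.parametrize("tau,rate", [(5000.0, 2e-4), (1.0, 1.0), (NOT_REACHED, 0.0)])
    def test_inverse_relation(self, tau, rate):
        assert sorting_rate(tau) == pytest.approx(rate)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            sorting_rate(0.0)


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fit_power_law(x, 10 * x**-1.5)
        assert fit.exponent == pytest.approx(-1.5)
        assert fit.amplitude == pytest.approx(10.0)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_constant_series_zero_exponent(self):
        fit = fit_power_law(np.array([1.0, 2.0, 3.0]), np.array([4.0, 4.0, 4.0]))
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_noisy_quadratic_recovered(self, rng):
        x = np.linspace(1, 10, 20)
        y = 3 * x**2 * (1 + rng.normal(0, 0.01, 20))
        fit = fit_power_law(x, y)
        assert 1.9 <= fit.exponent <= 2.1

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([1.0, 2.0, 3.0]), np.array([1.0, -2.0, 3.0]))


class TestRadialSortingIndex:
    @staticmethod
    def graded_shell_state(levels_in_to_out):
        """Single-pixel cells at strictly increasing radii from the center,
        one level per shell; level order vs radius is then unambiguous."""
        grid = np.zeros((45, 45), dtype=np.int32)
        # distances from the 4-cell centroid: 5.7 < 9.8 < 10.1 < 16.7
        positions = [(22, 24), (28, 22), (22, 10), (2, 22)]
        for i, (r, c) in enumerate(positions[: len(levels_in_to_out)]):
            grid[r, c] = i + 1
        return make_state(grid, list(levels_in_to_out))

    def test_perfect_inward_grading_scores_one(self):
        st = self.graded_shell_state([23.0, 17.5, 12.0, 1.0])
        assert radial_sorting_index(st) == pytest.approx(1.0)

    def test_inverted_grading_scores_minus_one(self):
        st = self.graded_shell_state([1.0, 12.0, 17.5, 23.0])
        assert radial_sorting_index(st) == pytest.approx(-1.0)

    def test_sorted_two_ring_aggregate_scores_high(self):
        # binary levels tie many ranks, so the ceiling is below 1; a fully
        # sorted two-ring aggregate must still score far above random
        size = 30
        grid = np.zeros((size, size), dtype=np.int32)
        rr, cc = np.mgrid[0:size, 0:size]
        d2 = (rr - 15.0) ** 2 + (cc - 15.0) ** 2
        ang = np.arctan2(rr - 15.0, cc - 15.0)
        for k in range(4):
            wedge = (ang >= -np.pi + k * np.pi / 2) & (ang < -np.pi + (k + 1) * np.pi / 2)
            grid[(d2 <= 36) & wedge] = k + 1
            grid[(d2 <= 144) & (d2 > 36) & wedge] = 5 + k
        st = make_state(grid, [23.0] * 4 + [1.0] * 4)
        assert radial_sorting_index(st) > 0.8

    def test_random_permutation_null_is_centered(self, rng):
        st = cs.build_circular_aggregate(
            40, 25, cs.get_scheme("levels5"), seed=3, relax_mcs=0
        )
        vals = []
        for _ in range(100):
            st.levels[1:] = rng.permutation(st.levels[1:])
            vals.append(radial_sorting_index(st))
        assert abs(np.mean(vals)) < 0.1
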