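"""Effective energy, incremental energy changes, acceptance rule."""

import math

import numpy as np
import pytest

import cadsort as cs
from cadsort.lattice import (
    acceptance_probability,
    apply_copy,
    delta_H,
    effective_energy,
    half_neighborhood_offsets,
    neighborhood_offsets,
)

from conftest import make_state, random_two_cell_state


def brute_force_energy(state, model, config):
    """Independent oracle: double loop over all site pairs with squared
    distance <= that of the neighbor order, energies from first principles."""
    max_d2 = {1: 1, 2: 2, 3: 4, 4: 5}[config.adhesion_neighbor_order]
    grid = state.grid
    h, w = grid.shape
    E = 0.0
    for r1 in range(h):
        for c1 in range(w):
            for r2 in range(h):
                for c2 in range(w):
                    if (r1, c1) >= (r2, c2):
                        continue
                    d2 = (r1 - r2) ** 2 + (c1 - c2) ** 2
                    if d2 > max_d2:
                        continue
                    a, b = int(grid[r1, c1]), int(grid[r2, c2])
                    if a == b:
                        continue
                    if a == 0 or b == 0:
                        E += config.J_cell_medium
                    else:
                        E += model.contact_energy(state.levels[a], state.levels[b])
    for i in range(1, state.n_cells + 1):
        E += config.lambda_vol * (state.volumes[i] - state.target_volumes[i]) ** 2
    return E


class TestNeighborhoods:
    def test_shell_counts(self):
        assert len(neighborhood_offsets(1)) == 4
        assert len(neighborhood_offsets(2)) == 8
        assert len(neighborhood_offsets(3)) == 12
        assert len(neighborhood_offsets(4)) == 20
        assert len(half_neighborhood_offsets(4)) == 10

    def test_half_set_is_involution_free(self):
        offs = {tuple(o) for o in half_neighborhood_offsets(4)}
        assert not any((-a, -b) in offs for a, b in offs)


class TestEffectiveEnergy:
    def test_all_medium_lattice_zero(self, thbm):
        st = make_state(np.zeros((6, 6), dtype=int), [])
        assert effective_energy(st, thbm, cs.SimulationConfig()) == 0.0

    def test_single_pixel_cell_counts_medium_links(self, thbm):
        cfg = cs.SimulationConfig(J_cell_medium=7.0)
        grid = np.zeros((9, 9), dtype=int)
        grid[4, 4] = 1
        st = make_state(grid, [5.0], target_volume=1)
        # all 20 order-<=4 neighbors are in-bounds medium sites; V = V_t
        assert effective_energy(st, thbm, cfg) == pytest.approx(20 * 7.0)
        assert effective_energy(st, thbm, cfg) == pytest.approx(
            brute_force_energy(st, thbm, cfg)
        )

    def test_two_adjacent_single_pixel_cells(self, thbm):
        cfg = cs.SimulationConfig(J_cell_medium=7.0)
        grid = np.zeros((5, 5), dtype=int)
        grid[2, 2] = 1
        grid[2, 3] = 2
        st = make_state(grid, [5.0, 5.0], target_volume=1)
        assert effective_energy(st, thbm, cfg) == pytest.approx(
            brute_force_energy(st, thbm, cfg)
        )

    @pytest.mark.parametrize("kind", ["CDM", "THBM", "SM"])
    @pytest.mark.parametrize("order", [1, 2, 4])
    def test_matches_brute_force_on_random_states(self, kind, order, rng):
        model = cs.BindingModel(kind, k_eff=0.03, delta_G=-1.0, J0=2.0)
        cfg = cs.SimulationConfig(adhesion_neighbor_order=order)
        for _ in range(3):
            st = random_two_cell_state(rng, size=10, n_cells=3)
            assert effective_energy(st, model, cfg) == pytest.approx(
                brute_force_energy(st, model, cfg)
            )

    def test_inconsistent_bookkeeping_detected(self, thbm):
        st = random_two_cell_state(np.random.default_rng(0))
        st.volumes[1] += 1
        with pytest.raises(RuntimeError):
            effective_energy(st, thbm, cs.SimulationConfig())


class TestDeltaH:
    def test_volume_gain_at_target(self, thbm):
        """A cell at target volume gaining a pixel pays lambda_vol exactly
        when adhesion is unchanged by symmetry."""
        cfg = cs.SimulationConfig(lambda_vol=3.0, J_cell_medium=5.0)
        grid = np.zeros((11, 11), dtype=int)
        grid[3:8, 3:8] = 1
        st = make_state(grid, [2.0])  # V = V_t = 25
        # medium site adjacent to the flat face: adhesion links swap
        # cell-medium for medium-cell symmetrically only in the volume term
        before = effective_energy(st, thbm, cfg)
        dH = delta_H(st, (5, 7), (5, 8), thbm, cfg)
        apply_copy(st, (5, 7), (5, 8))
        after = effective_energy(st, thbm, cfg)
        assert dH == pytest.approx(after - before)

    def test_same_index_rejected(self, thbm):
        grid = np.zeros((6, 6), dtype=int)
        grid[2:4, 2:4] = 1
        st = make_state(grid, [1.0])
        with pytest.raises(ValueError):
            delta_H(st, (2, 2), (2, 3), thbm, cs.SimulationConfig())

    @pytest.mark.parametrize("kind", ["CDM", "THBM", "SM"])
    def test_incremental_equals_full_recompute(self, kind, rng):
        """The central correctness oracle at unit-test scale."""
        model = cs.BindingModel(kind, k_eff=0.02, delta_G=-1.5, J0=3.0)
        cfg = cs.SimulationConfig()
        offs = neighborhood_offsets(cfg.copy_neighbor_order)
        for _ in range(4):
            st = random_two_cell_state(rng, size=12, n_cells=3)
            checked = 0
            while checked < 75:
                r, c = rng.integers(2, 10, 2)
                dr, dc = offs[rng.integers(0, len(offs))]
                src = (int(r + dr), int(c + dc))
                if st.grid[src] == st.grid[r, c]:
                    continue
                before = effective_energy(st, model, cfg)
                dH = delta_H(st, src, (r, c), model, cfg)
                work = st.copy()
                apply_copy(work, src, (r, c))
                after = effective_energy(work, model, cfg)
                assert dH == pytest.approx(after - before, abs=1e-9)
                checked += 1


class TestAcceptanceProbability:
    @pytest.mark.parametrize(
        "dH,T,expected",
        [(0.0, 20.0, 1.0), (-5.0, 1.0, 1.0), (20.0, 20.0, math.exp(-1))],
    )
    def test_metropolis_form(self, dH, T, expected):
        assert acceptance_probability(dH, T) == pytest.approx(expected)

    def test_detailed_balance_ratio(self):
        for dH in (0.5, 3.0, 17.2):
            T = 11.0
            ratio = acceptance_probability(dH, T) / acceptance_probability(-dH, T)
            assert ratio == pytest.approx(math.exp(-dH / T))

    def test_requires_positive_motility(self):
        with pytest.raises(ValueError):
            acceptance_probability(1.0, 0.0)


class TestSnapshotIO:
    def test_roundtrip(self, tmp_path, rng):
        st = random_two_cell_state(rng, size=10, n_cells=3, levels=[1.0, 12.0, 23.0])
        p = tmp_path / "snap.txt"
        st.save(p)
        back = cs.LatticeState.load(p)
        assert np.array_equal(back.grid, st.grid)
        assert np.allclose(back.levels, st.levels)
        assert np.array_equal(back.target_volumes, st.target_volumes)
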