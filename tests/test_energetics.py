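"""Energetics: closed-form potential values, brute-force oracles for total
and incremental energies, and cell-list equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brushsim.builder import make_micro_fixture, micro_fixture_names
from brushsim.energetics import (ContractViolation, Deletion, Displacement,
                                 GRAFT_SOLID, Insertion, ParticleSystem,
                                 all_pairs_within_cutoff, apply_move,
                                 bond_potential, build_cell_list,
                                 delta_energy, pair_potential, total_energy,
                                 wall_potential)
from brushsim.model import InteractionTable

from conftest import random_system


class TestPairPotential:
    def test_cutoff(self):
        assert pair_potential(1.0, 25.0) == 0.0
        assert pair_potential(1.7, 999.0) == 0.0

    def test_full_overlap(self):
        assert pair_potential(0.0, 25.0) == pytest.approx(12.5)

    def test_half_distance(self):
        assert pair_potential(0.5, 25.0) == pytest.approx(3.125)

    def test_continuity_at_cutoff(self):
        eps = 1e-8
        assert pair_potential(1.0 - eps, 25.0) < 1e-12

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_potential(-0.1, 25.0)

    @given(st.floats(0.0, 3.0), st.floats(0.0, 100.0))
    def test_non_negative(self, r, a):
        assert pair_potential(r, a) >= 0.0


class TestBondPotential:
    def test_rest_length(self):
        assert bond_potential(0.7, 100.0, 0.7) == 0.0

    def test_soft_value(self):
        assert bond_potential(0.1, 100.0, 0.0) == pytest.approx(0.5)

    def test_stiff_is_20x_soft(self):
        soft = bond_potential(0.1, 100.0, 0.0)
        stiff = bond_potential(0.1, 2000.0, 0.0)
        assert stiff == pytest.approx(10.0)
        assert stiff == pytest.approx(20.0 * soft)


class TestWallPotential:
    def test_cutoff(self):
        assert wall_potential(1.0, 25.0) == 0.0

    def test_contact(self):
        assert wall_potential(0.0, 25.0) == pytest.approx(12.5)

    def test_penetration(self):
        # soft wall allows negative gap; 12.5 * 1.2^2 = 18.0
        assert wall_potential(-0.2, 25.0) == pytest.approx(18.0)


def brute_force_energy(system, table, exclude_bonded=False):
    """Independent O(n^2) python-loop oracle."""
    Lx, Ly = system.box_xy
    pos = system.positions
    bonded = {(min(i, j), max(i, j)) for i, j in system.bonds}
    e_pair = 0.0
    for i in range(system.n):
        for j in range(i + 1, system.n):
            if exclude_bonded and (i, j) in bonded:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= Lx * round(dx / Lx)
            dy -= Ly * round(dy / Ly)
            r = (dx * dx + dy * dy + dz * dz) ** 0.5
            if r < 1.0:
                a = table.a[system.species[i], system.species[j]]
                e_pair += 0.5 * a * (1.0 - r) ** 2
    e_bond = 0.0
    for b, (i, j) in enumerate(system.bonds):
        d = pos[i] - pos[j]
        r = float(np.linalg.norm(d))
        e_bond += 0.5 * system.bond_kappa[b] * (r - system.bond_r0[b]) ** 2
    e_wall = 0.0
    for i in range(system.n):
        z = pos[i, 2]
        if z < 1.0:
            e_wall += 0.5 * table.a_wall_surface * (1.0 - z) ** 2
        g = system.h - z
        if g < 1.0:
            e_wall += 0.5 * table.a_wall_tip * (1.0 - g) ** 2
    return e_pair + e_bond + e_wall


class TestTotalEnergy:
    def test_empty_system(self, table2):
        eb = total_energy(ParticleSystem.empty(), table2)
        assert eb.total == 0.0

    def test_single_pair(self, table2):
        fix, system = make_micro_fixture("single-pair")
        eb = total_energy(system, table2)
        assert eb.pair == pytest.approx(3.125, abs=1e-10)
        assert eb.total == pytest.approx(fix.expected.total, abs=1e-10)

    @pytest.mark.parametrize("name", micro_fixture_names())
    def test_all_fixtures_match_hand_computation(self, name, table2):
        fix, system = make_micro_fixture(name)
        eb = total_energy(system, table2)
        assert eb.pair == pytest.approx(fix.expected.pair, abs=1e-10)
        assert eb.bond == pytest.approx(fix.expected.bond, abs=1e-10)
        assert eb.wall_surface == pytest.approx(fix.expected.wall_surface,
                                                abs=1e-10)
        assert eb.wall_tip == pytest.approx(fix.expected.wall_tip, abs=1e-10)

    def test_matches_brute_force_on_random_systems(self, table2):
        rng = np.random.default_rng(0)
        for trial in range(10):
            system = random_system(30, rng, with_chain=True)
            eb = total_energy(system, table2)
            assert eb.total == pytest.approx(
                brute_force_energy(system, table2), abs=1e-10)

    def test_breakdown_sums_to_total(self, table2):
        rng = np.random.default_rng(1)
        system = random_system(25, rng, with_chain=True)
        eb = total_energy(system, table2)
        assert eb.total == pytest.approx(
            eb.pair + eb.bond + eb.wall_surface + eb.wall_tip, rel=1e-10)

    def test_translation_invariance(self, table2):
        rng = np.random.default_rng(2)
        system = random_system(40, rng, with_chain=True)
        e0 = total_energy(system, table2).total
        shifted = system.copy()
        shifted.positions[:, 0] += 3.7
        shifted.positions[:, 1] -= 11.2
        e1 = total_energy(shifted, table2).total
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_exclude_bonded_switch(self, table2):
        _fix, system = make_micro_fixture("single-chain-3")
        eb = total_energy(system, table2, exclude_bonded=True)
        # only the non-bonded 1-3 pair at r = 0.2 remains: 12.5 * 0.64
        assert eb.pair == pytest.approx(8.0, abs=1e-10)
        assert eb.bond == pytest.approx(1.0, abs=1e-10)

    def test_non_negative(self, table2):
        rng = np.random.default_rng(3)
        for _ in range(5):
            system = random_system(20, rng)
            assert total_energy(system, table2).total >= 0.0


class TestDeltaEnergy:
    def test_null_move(self, table2):
        rng = np.random.default_rng(4)
        system = random_system(20, rng)
        mv = Displacement(3, system.positions[3].copy())
        assert delta_energy(system, mv, table2) == pytest.approx(0.0, abs=1e-12)

    def test_isolated_deletion(self, table2):
        system = ParticleSystem.solvent_only([[3.5, 3.5, 5.0]], (7.0, 7.0), 10.0)
        assert delta_energy(system, Deletion(0), table2) == 0.0

    def test_graft_solid_move_rejected(self, table2):
        rng = np.random.default_rng(5)
        system = random_system(10, rng)
        system.graft[2] = GRAFT_SOLID
        with pytest.raises(ContractViolation):
            delta_energy(system, Displacement(2, np.zeros(3)), table2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_full_recompute(self, seed, table2):
        rng = np.random.default_rng(seed)
        system = random_system(20, rng, with_chain=True)
        for _ in range(20):
            kind = rng.integers(3)
            if kind == 0:
                i = int(rng.integers(system.n))
                mv = Displacement(i, system.positions[i]
                                  + rng.normal(0, 0.4, 3))
                if not (0 <= mv.new_position[2] <= system.h):
                    continue
            elif kind == 1:
                p = rng.random(3) * np.array([7.0, 7.0, system.h])
                mv = Insertion(p)
            else:
                cand = np.flatnonzero(system.species == 0)
                mv = Deletion(int(rng.choice(cand)))
            before = total_energy(system, table2).total
            dU = delta_energy(system, mv, table2)
            after = total_energy(apply_move(system, mv), table2).total
            assert dU == pytest.approx(after - before, abs=1e-10)


class TestCellList:
    def test_single_bead(self):
        system = ParticleSystem.solvent_only([[3.0, 3.0, 3.0]], (7.0, 7.0), 8.0)
        cl = build_cell_list(system)
        assert cl.pairs(system.positions) == set()

    def test_periodic_edge_pair(self):
        system = ParticleSystem.solvent_only(
            [[1e-9, 3.0, 4.0], [7.0 - 1.0 + 2e-9, 3.0, 4.0]], (7.0, 7.0), 8.0)
        cl = build_cell_list(system)
        assert (0, 1) in cl.pairs(system.positions)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        system = random_system(50, rng)
        cl = build_cell_list(system)
        assert cl.pairs(system.positions) == all_pairs_within_cutoff(system)

    def test_small_box_fallback(self):
        rng = np.random.default_rng(9)
        system = random_system(15, rng, box_xy=(2.5, 2.5), h=2.0)
        cl = build_cell_list(system)
        assert cl.ncx == 1 and cl.ncy == 1
        assert cl.pairs(system.positions) == all_pairs_within_cutoff(system)


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(0, 10 ** 6), n=st.integers(2, 25))
def test_delta_energy_property(seed, n):
    """Randomized ΔU-vs-recompute agreement (hypothesis-driven)."""
    table = InteractionTable.default(1)
    rng = np.random.default_rng(seed)
    system = random_system(n, rng, with_chain=n >= 8)
    i = int(rng.integers(system.n))
    new = system.positions[i] + rng.normal(0, 0.5, 3)
    new[2] = float(np.clip(new[2], 0.0, system.h))
    mv = Displacement(i, new)
    before = total_energy(system, table).total
    dU = delta_energy(system, mv, table)
    after = total_energy(apply_move(system, mv), table).total
    assert dU == pytest.approx(after - before, abs=1e-10)
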