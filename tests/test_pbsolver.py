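"""LPB solver validation against closed-form electrostatics."""

import math

import numpy as np
import pytest

from pbtitrate.constants import COULOMB_KCAL, kappa2
from pbtitrate.pbsolver import (
    GridSpec,
    PBConfig,
    build_medium_map,
    focus,
    interaction_energy,
    reaction_field_energy,
    solve_focused,
    solve_lpb,
)
from pbtitrate.structure import Atom, Structure
from pbtitrate.synthetic import born_energy, make_born_ion


def uniform_medium(grid, eps=80.0, ionic_M=0.0):
    return build_medium_map(Structure(), grid, eps_in=eps, eps_out=eps,
                            ionic_strength_M=ionic_M)


GRID = GridSpec(center=(0, 0, 0), spacing=0.5, n_points=41)


class TestUniformMedium:
    def test_coulomb_potential(self):
        sol = solve_lpb(uniform_medium(GRID), [((0.0, 0.0, 0.0), 1.0)])
        for r in (1.5, 3.0, 5.0, 8.0):
            got = sol.evaluate([[r, 0, 0]])[0]
            want = COULOMB_KCAL / (80.0 * r)
            assert got == pytest.approx(want, rel=0.02 if r >= 1.5 else 0.05), r

    def test_debye_screened_potential(self):
        sol = solve_lpb(uniform_medium(GRID, ionic_M=0.1), [((0.0, 0.0, 0.0), 1.0)])
        kap = math.sqrt(kappa2(0.1, 80.0, 300.0))
        for r in (3.0, 5.0, 8.0):
            got = sol.evaluate([[r, 0, 0]])[0]
            want = COULOMB_KCAL * math.exp(-kap * r) / (80.0 * r)
            assert got == pytest.approx(want, rel=0.03), r

    def test_superposition(self):
        qa = [((-3.0, 0.0, 0.0), 1.0)]
        qb = [((3.0, 0.0, 0.0), -0.7)]
        med = uniform_medium(GRID)
        pa = solve_lpb(med, qa).phi
        pb = solve_lpb(med, qb).phi
        pab = solve_lpb(med, qa + qb).phi
        assert np.max(np.abs(pab - (pa + pb))) < 1e-4

    def test_charge_scaling_linearity(self):
        med = uniform_medium(GRID)
        p1 = solve_lpb(med, [((0.0, 0.0, 0.0), 1.0)]).phi
        p3 = solve_lpb(med, [((0.0, 0.0, 0.0), 3.0)]).phi
        assert np.max(np.abs(p3 - 3.0 * p1)) / np.max(np.abs(p3)) < 1e-6

    def test_zero_ionic_strength_means_no_screening(self):
        med = uniform_medium(GRID, ionic_M=0.0)
        assert np.all(med.screen == 0.0)

    def test_empty_structure_is_all_solvent(self):
        med = build_medium_map(Structure(), GRID, eps_in=4.0, eps_out=80.0)
        for eps in med.eps_edges:
            assert np.all(eps == 80.0)


class TestMediumMap:
    def test_interior_volume_matches_sphere(self):
        s = Structure()
        s.atoms.append(Atom(1, "X", "C", "SPH", "A", 1, np.zeros(3), 0.0, 2.0))
        grid = GridSpec(center=(0, 0, 0), spacing=0.5, n_points=33)
        med = build_medium_map(s, grid, eps_in=4.0, eps_out=80.0)
        # brute-force oracle: count x-edges whose midpoint is inside the sphere
        xs, ys, zs = grid.axes()
        mids = np.stack(np.meshgrid(xs[:-1] + 0.25, ys, zs, indexing="ij"), axis=-1)
        inside = np.linalg.norm(mids, axis=-1) < 2.0
        low_eps = med.eps_edges[0] < 42.0  # closer to eps_in than eps_out
        # boundary-smoothed edges may differ; interior bulk must agree
        assert np.sum(low_eps & inside) / np.sum(inside) > 0.9
        assert np.all(med.eps_edges[0][~inside & ~low_eps] == 80.0)

    def test_grid_too_small_raises(self):
        s = Structure()
        s.atoms.append(Atom(1, "X", "C", "SPH", "A", 1, np.zeros(3), 0.0, 2.0))
        tiny = GridSpec(center=(30, 0, 0), spacing=0.5, n_points=9)
        with pytest.raises(ValueError, match="too small"):
            build_medium_map(s, tiny)


class TestFocusing:
    def test_identical_child_reproduces_parent(self):
        med = uniform_medium(GRID)
        parent = solve_lpb(med, [((0.0, 0.0, 0.0), 1.0)])
        child = focus(parent, GRID, lambda g: uniform_medium(g),
                      [((0.0, 0.0, 0.0), 1.0)])
        assert np.max(np.abs(child.phi - parent.phi)) < 1e-4

    def test_child_outside_parent_raises(self):
        med = uniform_medium(GRID)
        parent = solve_lpb(med, [((0.0, 0.0, 0.0), 1.0)])
        big = GridSpec(center=(0, 0, 0), spacing=0.5, n_points=61)
        with pytest.raises(ValueError, match="beyond"):
            focus(parent, big, lambda g: uniform_medium(g), [((0.0, 0.0, 0.0), 1.0)])

    def test_focusing_error_decreases_monotonically(self):
        """2.5 -> 1.0 -> 0.3 A focusing converges toward the Born energy."""
        fx = make_born_ion(q=1.0, a=2.0)
        cfg = PBConfig()
        charges = [((0.0, 0.0, 0.0), 1.0)]
        from dataclasses import replace

        sol = solve_focused(fx.structure, charges, np.zeros(3), cfg)
        ref = solve_focused(fx.structure, charges, np.zeros(3),
                            replace(cfg, eps_out=4.0, ionic_strength_M=0.0))
        truth = fx.truth["reaction_energy_kcal_mol"]
        errs = []
        for lvl in range(3):
            dphi = sol.levels[lvl].evaluate([[0, 0, 0]])[0] - ref.levels[lvl].evaluate(
                [[0, 0, 0]]
            )[0]
            errs.append(abs(0.5 * dphi - truth))
        assert errs[0] > errs[1] > errs[2]

    def test_born_energy_within_two_percent(self):
        fx = make_born_ion(q=1.0, a=2.0)
        got = reaction_field_energy(fx.structure, [((0.0, 0.0, 0.0), 1.0)], PBConfig())
        assert got == pytest.approx(fx.truth["reaction_energy_kcal_mol"], rel=0.02)

    def test_born_quadratic_charge_scaling(self):
        cfg = PBConfig()
        e1 = reaction_field_energy(make_born_ion(q=1.0).structure,
                                   [((0.0, 0.0, 0.0), 1.0)], cfg)
        e2 = reaction_field_energy(make_born_ion(q=2.0).structure,
                                   [((0.0, 0.0, 0.0), 2.0)], cfg)
        assert e2 == pytest.approx(4.0 * e1, rel=1e-4)


class TestInteractionEnergy:
    def test_zero_probe_charges_give_exactly_zero(self):
        sol = solve_lpb(uniform_medium(GRID), [((0.0, 0.0, 0.0), 1.0)])
        assert interaction_energy(sol, [((3.0, 0.0, 0.0), 0.0)]) == 0.0
        assert interaction_energy(sol, []) == 0.0

    def test_unit_charges_ten_angstrom_apart(self):
        grid = GridSpec(center=(0, 0, 0), spacing=0.5, n_points=61)
        sol = solve_lpb(uniform_medium(grid), [((-5.0, 0.0, 0.0), 1.0)])
        got = interaction_energy(sol, [((5.0, 0.0, 0.0), 1.0)])
        assert got == pytest.approx(COULOMB_KCAL / 800.0, rel=0.02)

    def test_reciprocity(self):
        grid = GridSpec(center=(0, 0, 0), spacing=0.5, n_points=61)
        med = uniform_medium(grid)
        a = [((-5.0, 0.0, 0.0), 1.0)]
        b = [((5.0, 0.0, 0.0), 0.5)]
        e_ab = interaction_energy(solve_lpb(med, a), b)
        e_ba = interaction_energy(solve_lpb(med, b), a)
        assert abs(e_ab - e_ba) / abs(e_ab) < 0.005

    def test_probe_outside_grid_raises(self):
        sol = solve_lpb(uniform_medium(GRID), [((0.0, 0.0, 0.0), 1.0)])
        with pytest.raises(ValueError):
            sol.evaluate([[100.0, 0.0, 0.0]])

    def test_charge_outside_grid_raises(self):
        with pytest.raises(ValueError, match="outside"):
            solve_lpb(uniform_medium(GRID), [((100.0, 0.0, 0.0), 1.0)])
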