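"""Charge-deletion pKa decomposition: sign, zeroing, additivity."""

import numpy as np
import pytest

from pbtitrate.constants import COULOMB_KCAL, rt_ln10
from pbtitrate.decomposition import (
    additivity_check,
    contribution_table,
    contribution_tsv,
    residue_contribution_pka,
    resolve_perturber_atoms,
)
from pbtitrate.pbsolver import PBConfig
from pbtitrate.structure import Atom, Structure, TitratableSite

UNIFORM_WATER = PBConfig(eps_in=80.0, eps_out=80.0, ionic_strength_M=0.0)


def acid_with_charges(charges):
    """A single-atom acid at the origin plus fixed point charges."""
    s = Structure()
    s.atoms.append(Atom(1, "Q", "O", "ACD", "A", 1, np.zeros(3), 0.0, 0.0))
    for k, (pos, q) in enumerate(charges, start=2):
        s.atoms.append(Atom(k, "X", "N", "PRT", "A", k, np.asarray(pos, float), q, 0.0))
    site = TitratableSite(
        ("A", 1, "ACD"), "Asp", 4.0, {"Q": 0.0}, {"Q": -1.0},
        atoms_protonated={0: 0.0}, atoms_deprotonated={0: -1.0},
    )
    return s, site


class TestSingleContribution:
    def test_zero_charge_perturber_gives_exactly_zero(self):
        s, site = acid_with_charges([((5.0, 0.0, 0.0), 0.0)])
        rec = residue_contribution_pka(
            site, ("A", 2, "PRT"), s, [site], config=UNIFORM_WATER
        )
        assert rec.delta == 0.0

    def test_positive_charge_near_acid_lowers_pka(self):
        """Coulomb closed form: delta = -C/(80*5*RT ln10) for a +1 at 5 A."""
        s, site = acid_with_charges([((5.0, 0.0, 0.0), 1.0)])
        rec = residue_contribution_pka(
            site, ("A", 2, "PRT"), s, [site], config=UNIFORM_WATER
        )
        expected = -COULOMB_KCAL / (80.0 * 5.0 * rt_ln10(300.0))
        assert rec.delta < 0
        assert rec.delta == pytest.approx(expected, rel=0.10)

    def test_perturber_overlapping_target_raises(self):
        s, site = acid_with_charges([((5.0, 0.0, 0.0), 1.0)])
        with pytest.raises(ValueError, match="overlaps"):
            residue_contribution_pka(site, site, s, [site], config=UNIFORM_WATER)


class TestContributionTable:
    def test_empty_perturber_list_gives_baseline_row_only(self):
        s, site = acid_with_charges([])
        records = contribution_table(site, [], s, [site], config=UNIFORM_WATER)
        assert len(records) == 1
        assert records[0].perturber == "(baseline)"
        assert records[0].delta == 0.0

    def test_rows_match_independent_single_calls(self):
        charges = [((4.0, 0.0, 0.0), 1.0), ((0.0, 6.0, 0.0), -0.5),
                   ((0.0, 0.0, 8.0), 0.8)]
        s, site = acid_with_charges(charges)
        perturbers = [("A", k, "PRT") for k in (2, 3, 4)]
        records = contribution_table(site, perturbers, s, [site],
                                     config=UNIFORM_WATER)
        for rec, p in zip(records[1:], perturbers):
            single = residue_contribution_pka(site, p, s, [site],
                                              config=UNIFORM_WATER)
            assert rec.delta == pytest.approx(single.delta, abs=1e-9)

    def test_tsv_has_one_row_per_record(self):
        s, site = acid_with_charges([((5.0, 0.0, 0.0), 1.0)])
        records = contribution_table(site, [("A", 2, "PRT")], s, [site],
                                     config=UNIFORM_WATER)
        tsv = contribution_tsv(records)
        assert len(tsv.strip().splitlines()) == 1 + len(records)


class TestAdditivity:
    def test_fixed_background_additivity(self):
        """LPB linearity: disjoint deletions sum to the joint deletion."""
        charges = [((4.0, 0.0, 0.0), 1.0), ((0.0, 6.0, 0.0), -0.7)]
        s, site = acid_with_charges(charges)
        report = additivity_check(site, [("A", 2, "PRT"), ("A", 3, "PRT")],
                                  s, [site], config=UNIFORM_WATER)
        assert abs(report["deviation"]) < 0.05

    def test_single_perturber_is_trivially_additive(self):
        s, site = acid_with_charges([((5.0, 0.0, 0.0), 1.0)])
        report = additivity_check(site, [("A", 2, "PRT")], s, [site],
                                  config=UNIFORM_WATER)
        assert report["deviation"] == pytest.approx(0.0, abs=1e-12)

    def test_overlapping_perturbers_rejected(self):
        s, site = acid_with_charges([((5.0, 0.0, 0.0), 1.0)])
        with pytest.raises(ValueError, match="overlaps"):
            additivity_check(site, [("A", 2, "PRT"), ("A", 2, "PRT")],
                             s, [site], config=UNIFORM_WATER)

    def test_equilibrating_mode_reports_coupling_deviation(self):
        """With a second titratable site re-equilibrating, contributions need
        not be additive; the deviation is reported with its sign."""
        s, target = acid_with_charges(
            [((4.0, 0.0, 0.0), 1.0), ((0.0, 5.0, 0.0), 1.0)]
        )
        s.atoms.append(Atom(9, "Q", "O", "ACB", "A", 9,
                            np.array([0.0, 0.0, 3.5]), 0.0, 0.0))
        partner = TitratableSite(
            ("A", 9, "ACB"), "Glu", 4.4, {"Q": 0.0}, {"Q": -1.0},
            atoms_protonated={len(s.atoms) - 1: 0.0},
            atoms_deprotonated={len(s.atoms) - 1: -1.0},
        )
        report = additivity_check(
            target, [("A", 2, "PRT"), ("A", 3, "PRT")], s, [target, partner],
            config=UNIFORM_WATER, mode="equilibrating",
            ph_grid=np.arange(-4.0, 12.1, 0.25),
        )
        assert "deviation" in report
        assert np.isfinite(report["deviation"])


class TestPerturberResolution:
    def test_water_group(self):
        s, site = acid_with_charges([])
        s.atoms.append(Atom(10, "O", "O", "HOH", "W", 10, np.array([6.0, 0, 0])))
        s.atoms.append(Atom(11, "O", "O", "HOH", "W", 11, np.array([7.0, 0, 0])))
        label, atoms = resolve_perturber_atoms(s, "H2O")
        assert label == "H2O"
        assert len(atoms) == 2

    def test_sidechain_only_for_amino_acids(self):
        from conftest import make_peptide

        s = make_peptide(["ASP", "ALA"])
        label, atoms = resolve_perturber_atoms(s, ("A", 1, "ASP"))
        names = {s.atoms[i].name for i in atoms}
        assert names == {"CB", "CG", "OD1", "OD2"}  # backbone never deleted

    def test_missing_residue_raises(self):
        s, site = acid_with_charges([])
        with pytest.raises(ValueError, match="not found"):
            resolve_perturber_atoms(s, ("A", 99, "GLY"))
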