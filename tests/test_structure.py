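"""Structure I/O, parameter assignment, and titratable-site enumeration."""

import numpy as np
import pytest

from pbtitrate.hydrogens import place_hydrogens
from pbtitrate.parameters import (
    SITE_CLASSES,
    SITE_TEMPLATES,
    default_parameters,
    gamma,
)
from pbtitrate.structure import (
    PDBFormatError,
    apply_variants,
    assign_parameters,
    enumerate_titratable_sites,
    read_pdb,
    write_pdb,
)
from conftest import make_peptide, make_single_residue

PDB_3ATOMS = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.182  -4.916  1.00  0.00           C
END
"""


class TestReadPDB:
    def test_hand_written_file_round_trips_coordinates(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_3ATOMS)
        s = read_pdb(p)
        assert len(s) == 3
        np.testing.assert_allclose(
            s.atoms[0].position, [11.104, 6.134, -6.504], atol=1e-3
        )
        assert [a.name for a in s.atoms] == ["N", "CA", "C"]

    def test_malformed_coordinate_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(PDB_3ATOMS.replace("11.639", "xx.639"))
        with pytest.raises(PDBFormatError, match="line 2"):
            read_pdb(p)

    def test_missing_chain_raises(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_3ATOMS)
        with pytest.raises(ValueError, match="no atoms"):
            read_pdb(p, chain="B")

    def test_write_read_round_trip(self, tmp_path, tripeptide):
        out = tmp_path / "tri.pdb"
        write_pdb(tripeptide, out)
        back = read_pdb(out)
        assert len(back) == len(tripeptide)
        assert [a.name for a in back.atoms] == [a.name for a in tripeptide.atoms]
        np.testing.assert_allclose(
            back.positions(), tripeptide.positions(), atol=1e-3
        )

    def test_atom_count_matches_independent_parser(self, tmp_path, tripeptide):
        from Bio.PDB import PDBParser

        out = tmp_path / "tri.pdb"
        write_pdb(tripeptide, out)
        ours = len(read_pdb(out))
        ref = sum(
            1
            for _ in PDBParser(QUIET=True).get_structure("x", out).get_atoms()
        )
        assert ours == ref


class TestParameterTables:
    def test_neutral_forms_sum_to_zero(self):
        params = default_parameters()
        assert abs(sum(params.backbone_charges.values())) < 1e-6
        assert abs(sum(params.backbone_charges_pro.values())) < 1e-6
        for res, charges in params.sidechain_charges.items():
            assert abs(sum(charges.values())) < 1e-6, res

    def test_every_site_differs_by_one_proton(self):
        for res, templates in SITE_TEMPLATES.items():
            for cls, qp, qd in templates:
                assert sum(qp.values()) - sum(qd.values()) == pytest.approx(1.0), res

    def test_gamma_conventions(self):
        assert gamma("Asp", protonated=True) == 0.0
        assert gamma("Asp", protonated=False) == -1.0
        assert gamma("Lys", protonated=True) == 1.0
        assert gamma("Lys", protonated=False) == 0.0

    def test_reference_pkas(self):
        refs = {c: SITE_CLASSES[c][0] for c in SITE_CLASSES}
        assert refs["Arg"] == 12.0
        assert refs["Asp"] == 4.0
        assert refs["Cys"] == 9.5
        assert refs["Glu"] == 4.4
        assert refs["Lys"] == 10.4
        assert refs["Tyr"] == 9.6
        assert refs["His-Ne"] == 7.0
        assert refs["His-Nd"] == 6.6


class TestAssignParameters:
    def test_deprotonated_asp_sidechain_charge(self):
        s = place_hydrogens(make_single_residue("ASP"))
        sites = enumerate_titratable_sites(s, include_termini=False)
        (site,) = sites
        sp = assign_parameters(s, assignment={site.site_id: "deprotonated"})
        sc = sum(
            a.partial_charge for a in sp.atoms
            if a.name in ("CB", "CG", "OD1", "OD2")
        )
        assert sc == pytest.approx(-1.0)

    def test_protonated_asp_is_neutral(self):
        s = place_hydrogens(make_single_residue("ASP"))
        sites = enumerate_titratable_sites(s, include_termini=False)
        (site,) = sites
        sp = assign_parameters(s, assignment={site.site_id: "protonated"})
        sc = sum(
            a.partial_charge for a in sp.atoms
            if a.name in ("CB", "CG", "OD1", "OD2")
        )
        assert sc == pytest.approx(0.0)

    def test_flipping_one_site_changes_total_charge_by_one(self, tripeptide):
        s = place_hydrogens(tripeptide)
        sites = enumerate_titratable_sites(s)
        site = next(t for t in sites if t.site_class == "Asp")
        a = assign_parameters(s, assignment={site.key: "protonated"}, sites=sites)
        b = assign_parameters(s, assignment={site.key: "deprotonated"}, sites=sites)
        assert b.total_charge() - a.total_charge() == pytest.approx(-1.0)

    def test_all_protonated_vs_all_deprotonated(self, tripeptide):
        s = place_hydrogens(tripeptide)
        sites = enumerate_titratable_sites(s, include_termini=False)
        up = assign_parameters(
            s, assignment={t.key: "protonated" for t in sites}, sites=sites
        )
        down = assign_parameters(
            s, assignment={t.key: "deprotonated" for t in sites}, sites=sites
        )
        assert up.total_charge() - down.total_charge() == pytest.approx(len(sites))

    def test_every_atom_gets_a_radius(self, tripeptide):
        sp = assign_parameters(place_hydrogens(tripeptide))
        assert all(a.radius > 0 for a in sp.atoms)


class TestSiteEnumeration:
    def test_tripeptide_sidechain_sites(self, tripeptide):
        sites = enumerate_titratable_sites(tripeptide, include_termini=False)
        assert sorted(t.site_class for t in sites) == ["Asp", "Glu"]

    def test_termini_counted_when_atoms_present(self, tripeptide):
        s = place_hydrogens(make_peptide(["ASP", "ALA", "GLU"], oxt=True))
        sites = enumerate_titratable_sites(s)
        classes = sorted(t.site_class for t in sites)
        assert classes == ["Asp", "C-term", "Glu", "N-term"]

    def test_his_gives_two_subsites(self):
        s = place_hydrogens(make_single_residue("HIS"))
        sites = enumerate_titratable_sites(s, include_termini=False)
        assert sorted(t.site_class for t in sites) == ["His-Nd", "His-Ne"]
        assert sites[0].site_id == sites[1].site_id

    def test_mutated_residue_absent(self, tripeptide):
        mutant = apply_variants(tripeptide, [("A", 1, "ASP", "ASN")])
        sites = enumerate_titratable_sites(mutant, include_termini=False)
        assert [t.site_class for t in sites] == ["Glu"]
        names = {a.name for a in mutant.atoms if a.residue_number == 1}
        assert "ND2" in names and "OD2" not in names

    def test_unsupported_substitution_raises(self, tripeptide):
        with pytest.raises(ValueError, match="unsupported"):
            apply_variants(tripeptide, [("A", 1, "ASP", "GLU")])

    def test_fixed_request_for_non_titratable_raises(self, tripeptide):
        with pytest.raises(ValueError, match="non-titratable"):
            enumerate_titratable_sites(
                tripeptide, fixed={("A", 2, "ALA"): "fixed-protonated"}
            )
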