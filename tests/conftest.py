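"""Shared fixtures: crude-but-valid peptide geometries built in memory.

Geometric accuracy is deliberately rough (ideal-ish bond lengths); the
electrostatics tests rely on self-consistency (protein-vs-model-compound
cancellation), not on crystallographic geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

from pbtitrate.structure import Atom, Structure

# side-chain heavy atoms per residue, coordinates for a residue at the origin
_SIDECHAINS = {
    "ALA": {"CB": (2.0, -0.77, 1.25)},
    "ASP": {"CB": (2.0, -0.77, 1.25), "CG": (2.0, -0.3, 2.7),
            "OD1": (2.9, 0.5, 3.0), "OD2": (1.1, -0.8, 3.5)},
    "GLU": {"CB": (2.0, -0.77, 1.25), "CG": (2.0, -0.3, 2.7),
            "CD": (2.0, 0.2, 4.1), "OE1": (2.9, 1.0, 4.4), "OE2": (1.1, -0.3, 4.9)},
    "CYS": {"CB": (2.0, -0.77, 1.25), "SG": (2.0, 0.0, 2.9)},
    "SER": {"CB": (2.0, -0.77, 1.25), "OG": (2.0, -0.1, 2.6)},
    "TYR": {"CB": (2.0, -0.77, 1.25), "CG": (2.0, -0.3, 2.7),
            "CD1": (3.1, 0.3, 3.3), "CD2": (0.9, -0.9, 3.4),
            "CE1": (3.1, 0.5, 4.7), "CE2": (0.9, -0.7, 4.8),
            "CZ": (2.0, -0.1, 5.4), "OH": (2.0, 0.1, 6.8)},
    "LYS": {"CB": (2.0, -0.77, 1.25), "CG": (2.0, -0.3, 2.7),
            "CD": (2.0, 0.2, 4.1), "CE": (2.0, -0.4, 5.5), "NZ": (2.0, 0.1, 6.9)},
    "ARG": {"CB": (2.0, -0.77, 1.25), "CG": (2.0, -0.3, 2.7),
            "CD": (2.0, 0.2, 4.1), "NE": (2.0, -0.4, 5.5),
            "CZ": (2.3, 0.2, 6.7), "NH1": (3.5, 0.6, 6.9), "NH2": (1.5, 0.4, 7.8)},
    "HIS": {"CB": (2.0, -0.77, 1.25), "CG": (2.0, -0.3, 2.7),
            "ND1": (3.1, 0.2, 3.4), "CD2": (1.0, -0.9, 3.5),
            "CE1": (2.9, 0.0, 4.7), "NE2": (1.6, -0.7, 4.8)},
    "ASN": {"CB": (2.0, -0.77, 1.25), "CG": (2.0, -0.3, 2.7),
            "OD1": (2.9, 0.5, 3.0), "ND2": (1.1, -0.8, 3.5)},
}

_BACKBONE = {"N": (0.0, 0.0, 0.0), "CA": (1.46, 0.0, 0.0),
             "C": (2.0, 1.35, 0.0), "O": (1.35, 2.35, 0.0)}

_ELEMENTS = {"N": "N", "O": "O", "S": "S", "C": "C", "H": "H"}


def _element_of(name: str) -> str:
    return _ELEMENTS.get(name[0], "C")


def make_peptide(resnames, chain: str = "A", oxt: bool = False) -> Structure:
    """Build a stretched peptide with ~3.8 A CA-CA spacing along x."""
    s = Structure(provenance={"source": "synthetic-peptide"})
    serial = 0
    for i, resname in enumerate(resnames):
        off = np.array([3.8 * i, 0.0, 0.0])
        atoms = dict(_BACKBONE)
        atoms.update(_SIDECHAINS.get(resname, {}))
        for name, pos in atoms.items():
            serial += 1
            s.atoms.append(Atom(serial, name, _element_of(name), resname,
                                chain, i + 1, off + np.array(pos)))
        if oxt and i == len(resnames) - 1:
            serial += 1
            s.atoms.append(Atom(serial, "OXT", "O", resname, chain, i + 1,
                                off + np.array([3.0, 1.9, 0.4])))
    return s


def make_single_residue(resname: str) -> Structure:
    return make_peptide([resname])


@pytest.fixture
def tripeptide() -> Structure:
    return make_peptide(["ASP", "ALA", "GLU"])


@pytest.fixture
def alanine_dipeptide() -> Structure:
    return make_peptide(["ALA", "ALA"])
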