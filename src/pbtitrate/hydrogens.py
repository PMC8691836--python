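"""Geometric placement of polar hydrogens from residue templates.

Hydrogens are built at ideal bond lengths/angles from internal-coordinate
templates; heavy atoms are never moved.  Rotatable hydroxyl hydrogens
(Ser/Thr) are oriented by a 10-degree dihedral scan that minimizes the
distance to the nearest H-bond acceptor.  Titratable groups are built in
their ionized states (acids without the carboxyl proton, bases fully
protonated), matching the bundled charge set, so one placement pass
serves every protonation form.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .parameters import ParameterSet, default_parameters
from .structure import AMINO_ACIDS, WATER_NAMES, Atom, Structure


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector in hydrogen template")
    return v / n


def place_zmat(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position X with |X-p1| = bond, angle(X,p1,p2) = angle and
    dihedral(X,p1,p2,p3) = dihedral (NeRF construction)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    b1 = _unit(p1 - p2)
    n = _unit(np.cross(p2 - p3, b1))
    m = np.cross(n, b1)
    d = np.array(
        [-bond * math.cos(theta), -bond * math.sin(theta) * math.cos(phi),
         -bond * math.sin(theta) * math.sin(phi)]
    )
    return p1 + d[0] * b1 + d[1] * m + d[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return math.degrees(math.atan2(y, x))


def _bisector_h(x: np.ndarray, a: np.ndarray, b: np.ndarray, bond: float) -> np.ndarray:
    """In-plane H on atom x bonded to a and b (sp2 nitrogen geometry)."""
    d = -(_unit(a - x) + _unit(b - x))
    return x + bond * _unit(d)


# (H name, method, (parent, ref1, ref2), bond, [angle, dihedral])
_SIDECHAIN_H: Dict[str, Sequence[Tuple]] = {
    "LYS": (
        ("HZ1", "zmat", ("NZ", "CE", "CD"), 1.04, 109.5, 180.0),
        ("HZ2", "zmat", ("NZ", "CE", "CD"), 1.04, 109.5, 60.0),
        ("HZ3", "zmat", ("NZ", "CE", "CD"), 1.04, 109.5, -60.0),
    ),
    "ARG": (
        ("HE", "bisect", ("NE", "CD", "CZ"), 1.01),
        ("HH11", "zmat", ("NH1", "CZ", "NE"), 1.01, 120.0, 0.0),
        ("HH12", "zmat", ("NH1", "CZ", "NE"), 1.01, 120.0, 180.0),
        ("HH21", "zmat", ("NH2", "CZ", "NE"), 1.01, 120.0, 0.0),
        ("HH22", "zmat", ("NH2", "CZ", "NE"), 1.01, 120.0, 180.0),
    ),
    "HIS": (
        ("HD1", "bisect", ("ND1", "CG", "CE1"), 1.01),
        ("HE2", "bisect", ("NE2", "CD2", "CE1"), 1.01),
    ),
    "TRP": (("HE1", "bisect", ("NE1", "CD1", "CE2"), 1.01),),
    "ASN": (
        ("HD21", "zmat", ("ND2", "CG", "OD1"), 1.01, 120.0, 0.0),
        ("HD22", "zmat", ("ND2", "CG", "OD1"), 1.01, 120.0, 180.0),
    ),
    "GLN": (
        ("HE21", "zmat", ("NE2", "CD", "OE1"), 1.01, 120.0, 0.0),
        ("HE22", "zmat", ("NE2", "CD", "OE1"), 1.01, 120.0, 180.0),
    ),
    "SER": (("HG", "scan", ("OG", "CB", "CA"), 0.96, 108.5),),
    "THR": (("HG1", "scan", ("OG1", "CB", "CA"), 0.96, 108.5),),
}

_AMIDE_NH_BOND = 1.01
_NTERM_NH_BOND = 1.04


def _scan_dihedral(
    s: Structure, parent_i: int, p1, p2, p3, bond, angle, step_deg: float = 10.0
) -> np.ndarray:
    """Choose the hydroxyl dihedral minimizing the H...acceptor distance."""
    parent = s.atoms[parent_i]
    acceptors = []
    for a in s.atoms:
        if a.element not in ("O", "N"):
            continue
        d = float(np.linalg.norm(a.position - parent.position))
        if 1.5 < d < 3.5:
            acceptors.append(a.position)
    best_pos, best_score = None, math.inf
    for k in range(int(round(360.0 / step_deg))):
        pos = place_zmat(p1, p2, p3, bond, angle, k * step_deg)
        if not acceptors:
            score = abs(k * step_deg - 180.0)  # anti by default
        else:
            score = min(float(np.linalg.norm(pos - acc)) for acc in acceptors)
        if score < best_score:
            best_score, best_pos = score, pos
    return best_pos


def place_hydrogens(
    s: Structure,
    params: Optional[ParameterSet] = None,
    keep_existing: bool = True,
) -> Structure:
    """Add polar hydrogens; heavy atoms are left untouched.

    With ``keep_existing`` (default) hydrogens already present are kept
    and not rebuilt.  Residues without a template are skipped with a
    warning, listed under ``provenance['h_skipped']``.
    """
    params = params or default_parameters()
    out = s.copy()
    residues = out.residues
    keys = list(residues.keys())
    skipped: List[str] = []
    skipped_types: set = set()

    chain_first: Dict[str, Tuple] = {}
    prev_c: Dict[Tuple, Optional[int]] = {}
    last_c: Dict[str, Optional[int]] = {}
    for key in keys:
        if key[2] not in AMINO_ACIDS:
            continue
        chain_first.setdefault(key[0], key)
        prev_c[key] = last_c.get(key[0])
        for i in residues[key]:
            if out.atoms[i].name == "C":
                last_c[key[0]] = i

    new_atoms: List[Atom] = []

    def add_h(name: str, pos: np.ndarray, template_atom: Atom) -> None:
        new_atoms.append(
            Atom(
                serial=0, name=name, element="H",
                residue_name=template_atom.residue_name,
                chain_id=template_atom.chain_id,
                residue_number=template_atom.residue_number,
                position=pos,
            )
        )

    for key in keys:
        chain_id, resnum, resname = key
        if resname in WATER_NAMES:
            continue
        idxs = residues[key]
        by_name = {out.atoms[i].name: i for i in idxs}
        have = set(by_name)

        def pos_of(n: str):
            return out.atoms[by_name[n]].position

        if resname not in AMINO_ACIDS:
            if resname not in ("RET", "RSB"):
                skipped.append(f"{resname}{resnum}:{chain_id}")
                skipped_types.add(resname)
            continue

        is_first = key == chain_first.get(chain_id)
        templates = list(_SIDECHAIN_H.get(resname, ()))

        # backbone amide H / N-terminal ammonium
        if is_first:
            if {"N", "CA", "C"} <= have:
                for hname, dih in (("H1", 180.0), ("H2", 60.0), ("H3", -60.0)):
                    if keep_existing and hname in have:
                        continue
                    add_h(
                        hname,
                        place_zmat(pos_of("N"), pos_of("CA"), pos_of("C"),
                                   _NTERM_NH_BOND, 109.5, dih),
                        out.atoms[by_name["N"]],
                    )
        elif resname != "PRO" and {"N", "CA"} <= have and prev_c.get(key) is not None:
            if not (keep_existing and "H" in have):
                cprev = out.atoms[prev_c[key]].position
                add_h("H", _bisector_h(pos_of("N"), pos_of("CA"), cprev, _AMIDE_NH_BOND),
                      out.atoms[by_name["N"]])

        for tpl in templates:
            hname, method, refs = tpl[0], tpl[1], tpl[2]
            if keep_existing and hname in have:
                continue
            if not set(refs) <= have:
                skipped.append(f"{resname}{resnum}:{chain_id}/{hname}")
                skipped_types.add(f"{resname}/{hname}")
                continue
            p1, p2, p3 = (pos_of(n) for n in refs)
            parent_atom = out.atoms[by_name[refs[0]]]
            if method == "bisect":
                add_h(hname, _bisector_h(p1, p2, p3, tpl[3]), parent_atom)
            elif method == "zmat":
                add_h(hname, place_zmat(p1, p2, p3, tpl[3], tpl[4], tpl[5]), parent_atom)
            elif method == "scan":
                add_h(hname, _scan_dihedral(out, by_name[refs[0]], p1, p2, p3, tpl[3], tpl[4]),
                      parent_atom)

    out.atoms.extend(new_atoms)
    for i, a in enumerate(out.atoms, start=1):
        a.serial = i
    if skipped:
        out.provenance["h_skipped"] = ";".join(skipped)
        warnings.warn(
            f"no hydrogen template for {len(skipped)} residues/atoms "
            f"(types: {', '.join(sorted(skipped_types))}); "
            "see provenance['h_skipped']"
        )
    return out
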