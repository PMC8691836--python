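"""Bundled per-atom charges, radii, and reference pKa values.

The package ships a compact, self-consistent polar-hydrogen charge set
designed for continuum electrostatics: nonpolar hydrogens are implicit
(united atoms), polar groups carry localized partial charges, every
neutral protonation form sums to zero, and the protonated-minus-
deprotonated charge difference of every titratable site is exactly +1
(one proton).  Protonated acids are represented without an explicit
carboxyl hydrogen (the proton charge is smeared over the carboxylate),
which lets one hydrogen-placement pass (all titratable groups ionized)
serve every protonation form.  The whole table is data on a
:class:`ParameterSet` and can be swapped for another set.

Radii are van-der-Waals-flavored per-element values; they define the
dielectric boundary (union of atom spheres).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

# ---------------------------------------------------------------------------
# Site classes
# ---------------------------------------------------------------------------

#: site_class -> (reference model-compound pKa, "acid" | "base")
#: Acids are neutral when protonated; bases are neutral when deprotonated.
SITE_CLASSES: Dict[str, Tuple[float, str]] = {
    "Asp": (4.0, "acid"),
    "Glu": (4.4, "acid"),
    "Cys": (9.5, "acid"),
    "Tyr": (9.6, "acid"),
    "C-term": (3.8, "acid"),
    "Lys": (10.4, "base"),
    "Arg": (12.0, "base"),
    "His-Ne": (7.0, "base"),
    "His-Nd": (6.6, "base"),
    "N-term": (8.0, "base"),
    "SchiffBase": (7.0, "base"),
}


def gamma(site_class: str, protonated: bool) -> float:
    """Charge deviation of a site from its neutral form.

    Acids: protonated 0, deprotonated -1.  Bases: protonated +1,
    deprotonated 0.
    """
    kind = SITE_CLASSES[site_class][1]
    if kind == "acid":
        return 0.0 if protonated else -1.0
    return 1.0 if protonated else 0.0


# ---------------------------------------------------------------------------
# Backbone and side-chain base charges (neutral, non-titrating atoms)
# ---------------------------------------------------------------------------

BACKBONE_CHARGES: Dict[str, float] = {
    "N": -0.35,
    "H": 0.25,
    "CA": 0.10,
    "C": 0.55,
    "O": -0.55,
}

# Proline has no amide hydrogen.
BACKBONE_CHARGES_PRO: Dict[str, float] = {
    "N": -0.10,
    "CA": 0.10,
    "C": 0.55,
    "O": -0.55,
}

#: residue -> {atom name -> charge} for non-titrating side-chain polar groups.
#: Residues absent from this map have an uncharged side chain.
SIDECHAIN_CHARGES: Dict[str, Dict[str, float]] = {
    "SER": {"CB": 0.25, "OG": -0.65, "HG": 0.40},
    "THR": {"CB": 0.25, "OG1": -0.65, "HG1": 0.40},
    "ASN": {"CG": 0.55, "OD1": -0.55, "ND2": -0.60, "HD21": 0.30, "HD22": 0.30},
    "GLN": {"CD": 0.55, "OE1": -0.55, "NE2": -0.60, "HE21": 0.30, "HE22": 0.30},
    "TRP": {"NE1": -0.35, "HE1": 0.35},
    "MET": {"CG": 0.05, "SD": -0.10, "CE": 0.05},
    "HOH": {"O": -0.80, "H1": 0.40, "H2": 0.40},
}

#: Side-chain atom names per residue (heavy + polar H), used as the
#: charge-deletion group boundary; backbone atoms are never deleted.
SIDECHAIN_ATOMS: Dict[str, Tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "HE", "CZ", "NH1", "HH11", "HH12", "NH2", "HH21", "HH22"),
    "ASN": ("CB", "CG", "OD1", "ND2", "HD21", "HD22"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG", "HG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2", "HE21", "HE22"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "HD1", "CD2", "CE1", "NE2", "HE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ", "HZ1", "HZ2", "HZ3"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG", "HG"),
    "THR": ("CB", "OG1", "CG2", "HG1"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "HE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH", "HH"),
    "VAL": ("CB", "CG1", "CG2"),
}

# ---------------------------------------------------------------------------
# Titratable-site charge maps: atom -> charge for each protonation form.
# Invariant: sum(protonated) - sum(deprotonated) = +1 for every site.
# ---------------------------------------------------------------------------

#: residue -> list of (site_class, charges_protonated, charges_deprotonated)
SITE_TEMPLATES: Dict[str, Tuple[Tuple[str, Dict[str, float], Dict[str, float]], ...]] = {
    "ASP": (
        (
            "Asp",
            {"CG": 0.30, "OD1": -0.15, "OD2": -0.15},
            {"CG": 0.10, "OD1": -0.55, "OD2": -0.55},
        ),
    ),
    "GLU": (
        (
            "Glu",
            {"CD": 0.30, "OE1": -0.15, "OE2": -0.15},
            {"CD": 0.10, "OE1": -0.55, "OE2": -0.55},
        ),
    ),
    "CYS": (
        ("Cys", {"CB": 0.20, "SG": -0.20}, {"CB": 0.00, "SG": -1.00}),
    ),
    "TYR": (
        ("Tyr", {"CZ": 0.25, "OH": -0.25}, {"CZ": 0.10, "OH": -1.10}),
    ),
    "LYS": (
        (
            "Lys",
            {"NZ": -0.20, "HZ1": 0.40, "HZ2": 0.40, "HZ3": 0.40},
            {"NZ": -0.90, "HZ1": 0.30, "HZ2": 0.30, "HZ3": 0.30},
        ),
    ),
    "ARG": (
        (
            "Arg",
            {
                "NE": -0.40, "HE": 0.30, "CZ": 0.50,
                "NH1": -0.40, "HH11": 0.35, "HH12": 0.35,
                "NH2": -0.40, "HH21": 0.35, "HH22": 0.35,
            },
            {
                "NE": -0.55, "HE": 0.25, "CZ": 0.30,
                "NH1": -0.60, "HH11": 0.30, "HH12": 0.30,
                "NH2": -0.60, "HH21": 0.30, "HH22": 0.30,
            },
        ),
    ),
    # His is two coupled sub-sites; the non-titrating ring core carries +0.30
    # so that each neutral tautomer (one sub-site protonated, one
    # deprotonated) sums to zero and the imidazolium to +1.
    "HIS": (
        ("His-Ne", {"NE2": -0.10, "HE2": 0.45}, {"NE2": -0.65, "HE2": 0.00}),
        ("His-Nd", {"ND1": -0.10, "HD1": 0.45}, {"ND1": -0.65, "HD1": 0.00}),
    ),
}

#: Ring-core charges for His (non-titrating part of the side chain).
HIS_CORE_CHARGES: Dict[str, float] = {"CG": 0.10, "CD2": 0.10, "CE1": 0.10}

#: Retinal Schiff base (retinal covalently bound to the conserved lysine,
#: treated as one composite residue).  Site atoms: the Schiff-base nitrogen
#: NZ, its proton HZ, the retinal C15 and the lysine CE flanking it.  All
#: other retinal atoms are uncharged in this set.
SCHIFF_BASE_SITE: Tuple[str, Dict[str, float], Dict[str, float]] = (
    "SchiffBase",
    {"NZ": -0.10, "HZ": 0.40, "C15": 0.35, "CE": 0.35},
    {"NZ": -0.75, "HZ": 0.00, "C15": 0.35, "CE": 0.40},
)

#: N-terminal ammonium (replaces the backbone amide H with H1-H3).
NTERM_SITE: Tuple[str, Dict[str, float], Dict[str, float]] = (
    "N-term",
    {"N": -0.20, "H1": 0.40, "H2": 0.40, "H3": 0.40},
    {"N": -0.90, "H1": 0.30, "H2": 0.30, "H3": 0.30},
)

#: C-terminal carboxylate (overrides backbone C/O and adds OXT).
CTERM_SITE: Tuple[str, Dict[str, float], Dict[str, float]] = (
    "C-term",
    {"C": 0.30, "O": -0.15, "OXT": -0.15},
    {"C": 0.10, "O": -0.55, "OXT": -0.55},
)

# ---------------------------------------------------------------------------
# Radii
# ---------------------------------------------------------------------------

ELEMENT_RADII: Dict[str, float] = {
    "H": 1.00,
    "C": 1.90,
    "N": 1.625,
    "O": 1.48,
    "S": 1.85,
    "P": 1.87,
    "CL": 1.81,
    "NA": 1.36,
    "K": 1.76,
}
DEFAULT_RADIUS = 1.70


@dataclass
class ParameterSet:
    """Swappable container for the charge/radius/reference-pKa tables."""

    backbone_charges: Mapping[str, float] = field(default_factory=lambda: dict(BACKBONE_CHARGES))
    backbone_charges_pro: Mapping[str, float] = field(
        default_factory=lambda: dict(BACKBONE_CHARGES_PRO)
    )
    sidechain_charges: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in SIDECHAIN_CHARGES.items()}
    )
    sidechain_atoms: Mapping[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(SIDECHAIN_ATOMS)
    )
    site_templates: Mapping[str, Tuple] = field(default_factory=lambda: dict(SITE_TEMPLATES))
    his_core_charges: Mapping[str, float] = field(
        default_factory=lambda: dict(HIS_CORE_CHARGES)
    )
    element_radii: Mapping[str, float] = field(default_factory=lambda: dict(ELEMENT_RADII))
    default_radius: float = DEFAULT_RADIUS
    site_classes: Mapping[str, Tuple[float, str]] = field(
        default_factory=lambda: dict(SITE_CLASSES)
    )

    def radius_for(self, element: str, atom_name: str = "") -> float:
        return float(self.element_radii.get(element.upper(), self.default_radius))

    def reference_pka(self, site_class: str) -> float:
        return self.site_classes[site_class][0]

    def site_kind(self, site_class: str) -> str:
        return self.site_classes[site_class][1]


def default_parameters() -> ParameterSet:
    return ParameterSet()
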