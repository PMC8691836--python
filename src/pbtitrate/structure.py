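"""Structures, PDB I/O, parameter assignment, and titratable-site inventory.

A :class:`Structure` is a flat, ordered list of atoms with coordinates,
partial charges and radii -- the common substrate for all electrostatics
in this package.  PDB reading/writing is delegated to gemmi; charges and
radii come from a :class:`~pbtitrate.parameters.ParameterSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .parameters import (
    CTERM_SITE,
    NTERM_SITE,
    SCHIFF_BASE_SITE,
    ParameterSet,
    default_parameters,
)

ResidueKey = Tuple[str, int, str]  # (chain_id, residue_number, residue_name)
SiteId = Tuple[str, int, str]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL"}


class PDBFormatError(ValueError):
    pass


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # (3,) in Angstrom
    partial_charge: float = 0.0
    radius: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if self.radius < 0:
            raise ValueError(f"atom {self.name}: radius must be >= 0")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.residue_name)


@dataclass
class Structure:
    atoms: List[Atom] = field(default_factory=list)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> Dict[ResidueKey, List[int]]:
        """Ordered grouping of atom indices by residue."""
        out: Dict[ResidueKey, List[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    def total_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    def find_atom(self, chain_id: str, residue_number: int, name: str) -> Optional[int]:
        for i, a in enumerate(self.atoms):
            if (
                a.chain_id == chain_id
                and a.residue_number == residue_number
                and a.name == name
            ):
                return i
        return None

    def copy(self) -> "Structure":
        s = Structure(provenance=dict(self.provenance))
        for a in self.atoms:
            s.atoms.append(
                Atom(
                    a.serial, a.name, a.element, a.residue_name, a.chain_id,
                    a.residue_number, a.position.copy(), a.partial_charge, a.radius,
                )
            )
        return s

    def check_unique(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom identifier {key}")
            seen.add(key)


@dataclass
class TitratableSite:
    """One protonatable group with its two charge forms.

    ``charges_protonated`` / ``charges_deprotonated`` map atom names to
    charges (the spec-level view); ``atoms_protonated`` /
    ``atoms_deprotonated`` map atom *indices* in the parent structure,
    which disambiguates composite (multi-residue) sites.
    """

    site_id: SiteId
    site_class: str
    reference_pka: float
    charges_protonated: Dict[str, float]
    charges_deprotonated: Dict[str, float]
    fixed_state: str = "free"  # free | fixed-protonated | fixed-deprotonated
    atoms_protonated: Dict[int, float] = field(default_factory=dict)
    atoms_deprotonated: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        dq = sum(self.charges_protonated.values()) - sum(self.charges_deprotonated.values())
        if abs(dq - 1.0) > 1e-6:
            raise ValueError(
                f"site {self.site_id}: protonated-deprotonated charge difference "
                f"is {dq:.6f}, expected +1"
            )

    @property
    def key(self) -> Tuple[str, int, str, str]:
        """Unique key: site_id + site_class (a residue can host several sites)."""
        return (*self.site_id, self.site_class)

    @property
    def label(self) -> str:
        return f"{self.site_id[2]}{self.site_id[1]}{':' + self.site_id[0] if self.site_id[0] else ''}-{self.site_class}"

    def atom_indices(self) -> List[int]:
        return sorted(set(self.atoms_protonated) | set(self.atoms_deprotonated))

    def form_charges(self, protonated: bool) -> Dict[int, float]:
        return self.atoms_protonated if protonated else self.atoms_deprotonated

    def difference_charges(self) -> Dict[int, float]:
        """Protonated-minus-deprotonated charge per atom (sums to +1)."""
        out: Dict[int, float] = {}
        for i in self.atom_indices():
            out[i] = self.atoms_protonated.get(i, 0.0) - self.atoms_deprotonated.get(i, 0.0)
        return out


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _validate_pdb_text(path: Path) -> None:
    """Cheap pre-parse so malformed coordinate fields fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise PDBFormatError(
                            f"{path}: malformed coordinate field {fieldtxt!r} "
                            f"on line {lineno}"
                        ) from None


def read_pdb(
    path,
    chain: Optional[str] = None,
    model: int = 1,
    keep_waters: bool = True,
    keep_hetero: bool = True,
) -> Structure:
    """Read ATOM/HETATM records into a Structure.

    Only the requested model is read; ``chain`` restricts to one chain.
    Alternate locations keep the highest-occupancy conformer.  Charges
    and radii are left at zero until :func:`assign_parameters`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.remove_alternative_conformations()  # keeps highest occupancy
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    gmodel = st[model - 1 if model - 1 < len(st) else 0]
    out = Structure(provenance={"source": str(path), "model": str(model)})
    serial = 0
    for gchain in gmodel:
        if chain is not None and gchain.name != chain:
            continue
        for res in gchain:
            resname = res.name.strip()
            if resname in WATER_NAMES and not keep_waters:
                continue
            is_std = resname in AMINO_ACIDS or resname in WATER_NAMES
            if not is_std and not keep_hetero:
                continue
            for ga in res:
                serial += 1
                out.atoms.append(
                    Atom(
                        serial=serial,
                        name=ga.name.strip(),
                        element=ga.element.name.upper(),
                        residue_name=resname,
                        chain_id=gchain.name,
                        residue_number=res.seqid.num,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    )
                )
    if not out.atoms:
        raise ValueError(f"{path}: no atoms in selected chain {chain!r}")
    out.check_unique()
    return out


def write_pdb(s: Structure, path) -> None:
    # gemmi's add_residue/add_chain copy their argument, so each container
    # must be fully populated before it is added to its parent
    st = gemmi.Structure()
    st.name = s.provenance.get("source", "pbtitrate")
    by_chain: Dict[str, Dict[ResidueKey, List[Atom]]] = {}
    for a in s.atoms:
        by_chain.setdefault(a.chain_id or "A", {}).setdefault(a.residue_key, []).append(a)
    gmodel = gemmi.Model("1")
    for chain_id, residues in by_chain.items():
        chain = gemmi.Chain(chain_id)
        for key, atoms in residues.items():
            res = gemmi.Residue()
            res.name = key[2]
            res.seqid = gemmi.SeqId(key[1], " ")
            res.het_flag = "A" if key[2] in AMINO_ACIDS else "H"
            for a in atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.position)
                ga.occ = 1.0
                ga.b_iso = 0.0
                res.add_atom(ga)
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

def _base_charge(
    atom: Atom,
    residue_atoms: Sequence[Atom],
    params: ParameterSet,
    is_nterm: bool,
    is_cterm: bool,
) -> float:
    resname = atom.residue_name
    name = atom.name
    if resname not in AMINO_ACIDS and resname not in WATER_NAMES:
        # unparameterized (hetero / synthetic) residues keep their charges
        return atom.partial_charge
    if resname in WATER_NAMES:
        has_h = any(a.element == "H" for a in residue_atoms)
        if name.startswith("O"):
            return -0.80 if has_h else 0.0
        if atom.element == "H":
            return 0.40
        return 0.0
    if resname in AMINO_ACIDS:
        bb = params.backbone_charges_pro if resname == "PRO" else params.backbone_charges
        if name in bb and not (is_nterm and name in ("N", "H")) and not (
            is_cterm and name in ("C", "O")
        ):
            return float(bb[name])
        if resname == "HIS" and name in params.his_core_charges:
            return float(params.his_core_charges[name])
        sc = params.sidechain_charges.get(resname, {})
        if name in sc:
            return float(sc[name])
        return 0.0
    return 0.0


def assign_parameters(
    s: Structure,
    params: Optional[ParameterSet] = None,
    assignment: Optional[Mapping[SiteId, str]] = None,
    sites: Optional[List[TitratableSite]] = None,
) -> Structure:
    """Assign a charge and radius to every atom.

    ``assignment`` maps site ids to ``"protonated"``/``"deprotonated"``;
    unassigned titratable sites take their charge-neutral form (acids
    protonated, bases deprotonated).  Returns a modified copy.
    """
    params = params or default_parameters()
    out = s.copy()
    if sites is None:
        sites = enumerate_titratable_sites(out, params, _check_params=False)
    assignment = dict(assignment or {})

    residues = out.residues
    for key, idxs in residues.items():
        res_atoms = [out.atoms[i] for i in idxs]
        is_nterm = any(a.name in ("H1", "H2", "H3") for a in res_atoms)
        is_cterm = any(a.name == "OXT" for a in res_atoms)
        known = key[2] in AMINO_ACIDS or key[2] in WATER_NAMES
        for i in idxs:
            a = out.atoms[i]
            a.partial_charge = _base_charge(a, res_atoms, params, is_nterm, is_cterm)
            # hetero/synthetic residues keep radii their builder set
            if known or a.radius == 0.0:
                a.radius = params.radius_for(a.element, a.name)

    for site in sites:
        # keys may be site.key (unique) or site.site_id (whole residue)
        form = assignment.get(site.key, assignment.get(site.site_id))
        if form is None:
            form = "protonated" if params.site_kind(site.site_class) == "acid" else "deprotonated"
        if form not in ("protonated", "deprotonated"):
            raise ValueError(f"unknown protonation form {form!r} for {site.site_id}")
        for i, q in site.form_charges(form == "protonated").items():
            out.atoms[i].partial_charge = q
    return out


# ---------------------------------------------------------------------------
# Titratable-site enumeration
# ---------------------------------------------------------------------------

def _index_map(
    s: Structure, idxs: Sequence[int], name_charges: Mapping[str, float], where: str
) -> Dict[int, float]:
    by_name = {s.atoms[i].name: i for i in idxs}
    out = {}
    for name, q in name_charges.items():
        if name in by_name:
            out[by_name[name]] = q
        elif abs(q) > 0:
            raise ValueError(f"{where}: charged atom {name} missing from structure")
    return out


def enumerate_titratable_sites(
    s: Structure,
    params: Optional[ParameterSet] = None,
    fixed: Optional[Mapping[SiteId, str]] = None,
    include_termini: bool = True,
    schiff_base_state: str = "fixed-protonated",
    _check_params: bool = True,
) -> List[TitratableSite]:
    """Enumerate every titratable group in the structure.

    Asp/Glu/His/Lys/Arg/Cys/Tyr side chains, chain termini (when their
    atoms are present), and the retinal Schiff base (fixed-protonated by
    default).  Mutated residues (e.g. Asn replacing Asp) simply do not
    match any template and are absent.
    """
    params = params or default_parameters()
    fixed = dict(fixed or {})
    sites: List[TitratableSite] = []
    residues = s.residues
    keys = list(residues.keys())

    chain_first: Dict[str, ResidueKey] = {}
    chain_last: Dict[str, ResidueKey] = {}
    for key in keys:
        if key[2] in AMINO_ACIDS:
            chain_first.setdefault(key[0], key)
            chain_last[key[0]] = key

    def build(
        key: ResidueKey, template, idxs: Sequence[int], state: str
    ) -> TitratableSite:
        cls, qp, qd = template
        return TitratableSite(
            site_id=key,
            site_class=cls,
            reference_pka=params.reference_pka(cls),
            charges_protonated=dict(qp),
            charges_deprotonated=dict(qd),
            fixed_state=state,
            atoms_protonated=_index_map(s, idxs, qp, f"{key}/{cls}"),
            atoms_deprotonated=_index_map(s, idxs, qd, f"{key}/{cls}"),
        )

    ret_keys = [k for k in keys if k[2] in ("RET", "RSB")]

    for key in keys:
        chain_id, resnum, resname = key
        idxs = residues[key]
        for template in params.site_templates.get(resname, ()):
            state = fixed.get(key, "free")
            sites.append(build(key, template, idxs, state))
        if include_termini and resname in AMINO_ACIDS:
            names = {s.atoms[i].name for i in idxs}
            if key == chain_first.get(chain_id) and {"H1", "H2", "H3"} <= names:
                sites.append(build(key, NTERM_SITE, idxs, fixed.get(key, "free")))
            if key == chain_last.get(chain_id) and "OXT" in names:
                sites.append(build(key, CTERM_SITE, idxs, fixed.get(key, "free")))

    # Retinal Schiff base: either a single composite residue (RSB) or a RET
    # residue covalently linked to a nearby lysine NZ.
    for key in ret_keys:
        idxs = list(residues[key])
        names = {s.atoms[i].name for i in idxs}
        if key[2] == "RET" and "NZ" not in names:
            c15 = next((i for i in idxs if s.atoms[i].name == "C15"), None)
            if c15 is not None:
                best = None
                for lkey, lidxs in residues.items():
                    if lkey[2] != "LYS":
                        continue
                    for j in lidxs:
                        if s.atoms[j].name == "NZ":
                            d = float(np.linalg.norm(s.atoms[j].position - s.atoms[c15].position))
                            if d < 2.0 and (best is None or d < best[0]):
                                best = (d, lkey)
                if best is not None:
                    idxs = idxs + list(residues[best[1]])
        state = fixed.get(key, schiff_base_state)
        sites.append(build(key, SCHIFF_BASE_SITE, idxs, state))

    for key, state in fixed.items():
        if not any(site.site_id == key for site in sites):
            raise ValueError(f"fixed-state request for non-titratable residue {key}")
    return sites


def site_inventory_table(sites: Iterable[TitratableSite]) -> str:
    """TSV inventory: site_id, class, reference pKa, fixed state."""
    lines = ["chain\tresnum\tresname\tsite_class\treference_pka\tfixed_state"]
    for t in sites:
        c, n, r = t.site_id
        lines.append(f"{c}\t{n}\t{r}\t{t.site_class}\t{t.reference_pka:.2f}\t{t.fixed_state}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_VARIANT_ATOM_MAPS = {
    ("ASP", "ASN"): {"OD2": "ND2"},
    ("GLU", "GLN"): {"OE2": "NE2"},
    ("GLU", "ASP"): {"CD": "CG", "OE1": "OD1", "OE2": "OD2"},
}
_VARIANT_DROPS = {("GLU", "ASP"): {"CG"}}


def apply_variants(
    s: Structure, variants: Sequence[Tuple[str, int, str, str]]
) -> Structure:
    """Apply point substitutions given as (chain, resnum, from, to) 3-letter codes.

    Only charge-conservative, atom-removing substitutions are supported
    (Asp->Asn, Glu->Gln, Glu->Asp); substitutions that would require
    building new heavy atoms need an externally supplied mutant structure.
    Re-run hydrogen placement afterwards to add e.g. amide hydrogens.
    """
    out = s.copy()
    for chain, resnum, from3, to3 in variants:
        from3, to3 = from3.upper(), to3.upper()
        pair = (from3, to3)
        if pair not in _VARIANT_ATOM_MAPS:
            raise ValueError(
                f"unsupported substitution {from3}->{to3}: requires building heavy "
                "atoms; supply a mutant structure instead"
            )
        matched = False
        drops = _VARIANT_DROPS.get(pair, set())
        kept = []
        for a in out.atoms:
            if a.chain_id == chain and a.residue_number == resnum and a.residue_name == from3:
                matched = True
                if a.name in drops:
                    continue
                a.name = _VARIANT_ATOM_MAPS[pair].get(a.name, a.name)
                a.residue_name = to3
            kept.append(a)
        out.atoms = kept
        if not matched:
            raise ValueError(f"variant target {from3}{resnum}:{chain} not found")
    vlist = ",".join(f"{f}{n}{t}" for _, n, f, t in variants)
    out.provenance["variant"] = (out.provenance.get("variant", "") + "+" + vlist).lstrip("+")
    return out


def read_variant_tsv(path) -> List[Tuple[str, int, str, str]]:
    """Parse a variant TSV: chain, resnum, from-residue, to-residue."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chain"):
                continue
            chain, resnum, from3, to3 = line.split("\t")
            out.append((chain, int(resnum), from3, to3))
    return out
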