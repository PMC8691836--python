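"""Synthetic fixtures with analytic ground truth.

Every stage of the pipeline is testable without downloads: Born ions and
charge pairs validate the PB solver against closed forms; titration toys
with known intrinsic pKas and couplings validate the sampler and curve
analysis; a mock protonated-Schiff-base/diacid system emulates the
counterion arrangement of an anion channelrhodopsin (a fixed +1 charge
with two titratable acids at 3.2 and 5.3 A inside a low-dielectric
sphere); cylindrical atom shells validate the pore profiler.  Sidecar
truth values are computed by closed form or enumeration only -- never by
the code under test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import COULOMB_KCAL
from .structure import Atom, Structure, TitratableSite, write_pdb
from .titration import SiteEnergetics


@dataclass
class Fixture:
    structure: Structure
    sites: List[TitratableSite] = field(default_factory=list)
    truth: Dict = field(default_factory=dict)
    energetics: Optional[SiteEnergetics] = None


def born_energy(q: float, a: float, eps_in: float, eps_out: float) -> float:
    """Closed-form Born reaction-field energy, kcal/mol."""
    return (COULOMB_KCAL / (2.0 * a)) * q * q * (1.0 / eps_out - 1.0 / eps_in)


def make_born_ion(
    q: float = 1.0, a: float = 2.0, eps_in: float = 4.0, eps_out: float = 80.0
) -> Fixture:
    """One ion of radius ``a`` and charge ``q`` at the origin."""
    if a <= 0:
        raise ValueError("Born radius must be > 0")
    s = Structure(provenance={"fixture": "born_ion"})
    s.atoms.append(Atom(1, "ION", "C", "BRN", "A", 1, np.zeros(3), q, a))
    return Fixture(
        structure=s,
        truth={
            "reaction_energy_kcal_mol": born_energy(q, a, eps_in, eps_out),
            "eps_in": eps_in,
            "eps_out": eps_out,
        },
    )


def make_charge_pair(d: float = 10.0, q1: float = 1.0, q2: float = 1.0,
                     eps: float = 80.0) -> Fixture:
    """Two point charges in uniform dielectric (zero-radius atoms)."""
    s = Structure(provenance={"fixture": "charge_pair"})
    s.atoms.append(Atom(1, "Q1", "C", "CHG", "A", 1, np.zeros(3), q1, 0.0))
    s.atoms.append(Atom(2, "Q2", "C", "CHG", "A", 2, np.array([d, 0.0, 0.0]), q2, 0.0))
    return Fixture(
        structure=s,
        truth={"coulomb_energy_kcal_mol": COULOMB_KCAL * q1 * q2 / (eps * d), "eps": eps},
    )


# ---------------------------------------------------------------------------
# Titration toys
# ---------------------------------------------------------------------------

def _embed_distances(d: np.ndarray) -> np.ndarray:
    """Classical multidimensional scaling of a distance matrix into 3D."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:3]
    lam = np.clip(vals[order], 0.0, None)
    pos = vecs[:, order] * np.sqrt(lam)[None, :]
    if pos.shape[1] < 3:
        pos = np.hstack([pos, np.zeros((n, 3 - pos.shape[1]))])
    return pos


def make_titration_toy(
    pka_intr: Sequence[float],
    W: Optional[np.ndarray] = None,
    kinds: Optional[Sequence[str]] = None,
    temperature_K: float = 300.0,
    eps: float = 80.0,
    geometry: bool = True,
) -> Fixture:
    """A toy multi-site titratable system with a prescribed Hamiltonian.

    The truth :class:`SiteEnergetics` is exactly the requested one.  When
    ``geometry`` is set, single-atom acid sites are embedded in uniform
    dielectric at separations back-solved from Coulomb's law
    (d_ij = C / (eps W_ij)), so the PB pipeline should reproduce the
    requested couplings; this requires all W_ij > 0 and an embeddable
    distance matrix (infeasible requests raise with the offending pair).
    """
    pka_intr = np.asarray(pka_intr, dtype=float)
    n = len(pka_intr)
    if n > 12:
        raise ValueError("toy systems limited to 12 sites")
    if W is None:
        W = np.zeros((n, n))
    W = np.asarray(W, dtype=float)
    kinds = list(kinds) if kinds is not None else ["acid"] * n
    energetics = SiteEnergetics(
        labels=[f"toy{i}" for i in range(n)],
        kinds=kinds,
        pka_intrinsic=pka_intr,
        W=W.copy(),
        temperature_K=temperature_K,
    )
    fixture = Fixture(structure=Structure(provenance={"fixture": "titration_toy"}),
                      energetics=energetics,
                      truth={"pka_intrinsic": pka_intr.tolist(), "W": W.tolist()})
    if not geometry:
        return fixture
    if n > 1:
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if W[i, j] <= 0:
                    raise ValueError(
                        f"infeasible geometry: W[{i},{j}] = {W[i, j]} <= 0 cannot be "
                        "realized by like-charged point sites"
                    )
                d[i, j] = d[j, i] = COULOMB_KCAL / (eps * W[i, j])
        pos = _embed_distances(d)
        got = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        for i in range(n):
            for j in range(i + 1, n):
                if abs(got[i, j] - d[i, j]) > 0.02 * d[i, j] + 1e-9:
                    raise ValueError(
                        f"infeasible geometry: requested W cannot be embedded in 3D "
                        f"(pair {i},{j}: wanted {d[i, j]:.3f} A, best {got[i, j]:.3f} A)"
                    )
    else:
        pos = np.zeros((1, 3))
    s = fixture.structure
    for i in range(n):
        s.atoms.append(Atom(i + 1, "Q", "C", "TOY", "A", i + 1, pos[i], 0.0, 0.0))
        fixture.sites.append(
            TitratableSite(
                site_id=("A", i + 1, "TOY"),
                site_class="Asp" if kinds[i] == "acid" else "Lys",
                reference_pka=float(pka_intr[i]),
                charges_protonated={"Q": 0.0} if kinds[i] == "acid" else {"Q": 1.0},
                charges_deprotonated={"Q": -1.0} if kinds[i] == "acid" else {"Q": 0.0},
                atoms_protonated={i: 0.0} if kinds[i] == "acid" else {i: 1.0},
                atoms_deprotonated={i: -1.0} if kinds[i] == "acid" else {i: 0.0},
            )
        )
    return fixture


# Overriding the reference pKa of toy sites keeps the uniform-dielectric
# PB route consistent: with no cavity and no background, every shift cancels
# and the intrinsic pKa equals the (requested) reference value.


# ---------------------------------------------------------------------------
# Mock Schiff base / counterion diad
# ---------------------------------------------------------------------------

def make_mock_schiffbase(
    d_near: float = 3.2,
    d_far: float = 5.3,
    d_acids: float = 4.5,
    sphere_radius: float = 12.0,
    filler_spacing: float = 2.8,
    filler_radius: float = 1.9,
    acid_radius: float = 1.9,
    acid_refs: Tuple[float, float] = (4.0, 4.4),
) -> Fixture:
    """A fixed +1 'Schiff base' with two titratable acids in a dielectric sphere.

    Geometry mimics the counterion arrangement at a protonated retinal
    Schiff base: the near acid (Asp-like, reference pKa 4.0) sits
    ``d_near`` from the +1 charge, the far acid (Glu-like, 4.4) at
    ``d_far``, the two acids ``d_acids`` apart, all inside a
    low-dielectric sphere of neutral filler atoms.  The expected behavior
    is that the near acid titrates far below the far acid and at pH 7 the
    pattern is near-deprotonated / far-protonated.
    """
    if not (2.0 < d_near <= d_far):
        raise ValueError("require 2 < d_near <= d_far")
    if d_acids >= d_near + d_far and abs(d_near - d_far) >= d_acids:
        raise ValueError("acid-acid distance violates the triangle inequality")

    p_sb = np.zeros(3)
    # acids placed symmetrically about the x-axis so that d_near == d_far
    # yields a mirror-symmetric fixture (the Schiff-base group below is
    # symmetric under y -> -y as well)
    cos_t = (d_near**2 + d_far**2 - d_acids**2) / (2.0 * d_near * d_far)
    half = 0.5 * math.acos(float(np.clip(cos_t, -1.0, 1.0)))
    p_near = d_near * np.array([math.cos(half), -math.sin(half), 0.0])
    p_far = d_far * np.array([math.cos(half), math.sin(half), 0.0])

    s = Structure(provenance={"fixture": "mock_schiffbase"})
    # composite Schiff-base group (atom names match the bundled site template)
    sb_atoms = {
        "NZ": p_sb,
        "HZ": p_sb + np.array([0.0, 0.0, 1.0]),
        "C15": p_sb + np.array([-1.2, 0.0, -0.8]),
        "CE": p_sb + np.array([1.2, 0.0, -0.8]),
    }
    serial = 0
    for name, pos in sb_atoms.items():
        serial += 1
        elem = "H" if name == "HZ" else ("N" if name == "NZ" else "C")
        s.atoms.append(Atom(serial, name, elem, "RSB", "A", 1,
                            pos, 0.0, 1.0 if elem == "H" else 1.9))
    serial += 1
    near_idx = serial - 1
    s.atoms.append(Atom(serial, "Q", "O", "NEA", "A", 2, p_near, 0.0, acid_radius))
    serial += 1
    far_idx = serial - 1
    s.atoms.append(Atom(serial, "Q", "O", "FAA", "A", 3, p_far, 0.0, acid_radius))

    functional = [a.position for a in s.atoms]
    m = int(math.ceil(sphere_radius / filler_spacing))
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for k in range(-m, m + 1):
                p = filler_spacing * np.array([i, j, k], dtype=float)
                if np.linalg.norm(p) > sphere_radius - filler_radius:
                    continue
                if min(float(np.linalg.norm(p - f)) for f in functional) < 2.5:
                    continue
                serial += 1
                s.atoms.append(Atom(serial, "FIL", "C", "FIL", "A", 100 + serial,
                                    p, 0.0, filler_radius))

    sb_index = {a.name: i for i, a in enumerate(s.atoms[:4])}
    from .parameters import SCHIFF_BASE_SITE

    cls, qp, qd = SCHIFF_BASE_SITE
    sites = [
        TitratableSite(
            site_id=("A", 1, "RSB"), site_class=cls, reference_pka=7.0,
            charges_protonated=dict(qp), charges_deprotonated=dict(qd),
            fixed_state="fixed-protonated",
            atoms_protonated={sb_index[n]: q for n, q in qp.items()},
            atoms_deprotonated={sb_index[n]: q for n, q in qd.items()},
        ),
        TitratableSite(
            site_id=("A", 2, "NEA"), site_class="Asp", reference_pka=acid_refs[0],
            charges_protonated={"Q": 0.0}, charges_deprotonated={"Q": -1.0},
            atoms_protonated={near_idx: 0.0}, atoms_deprotonated={near_idx: -1.0},
        ),
        TitratableSite(
            site_id=("A", 3, "FAA"), site_class="Glu", reference_pka=acid_refs[1],
            charges_protonated={"Q": 0.0}, charges_deprotonated={"Q": -1.0},
            atoms_protonated={far_idx: 0.0}, atoms_deprotonated={far_idx: -1.0},
        ),
    ]
    return Fixture(
        structure=s,
        sites=sites,
        truth={
            "d_near_A": d_near,
            "d_far_A": d_far,
            "d_acids_A": d_acids,
            "expected_order": "pka(near) < pka(far)",
            "expected_pattern_pH7": {"near": "deprotonated", "far": "protonated"},
        },
    )


# ---------------------------------------------------------------------------
# Cylindrical pore
# ---------------------------------------------------------------------------

def make_cylinder_pore(
    R: float = 4.0,
    L: float = 20.0,
    atom_radius: float = 1.7,
    ring_spacing: float = 1.2,
    bump: Optional[Tuple[float, float, float]] = None,
) -> Fixture:
    """Atom shell forming a cylindrical pore of inner radius ``R`` along z.

    ``bump``, if given, is (z_height, lateral_offset, atom_radius) for one
    extra atom narrowing the pore locally.
    """
    if R <= 0 or L <= 0:
        raise ValueError("R and L must be > 0")
    s = Structure(provenance={"fixture": "cylinder_pore"})
    shell_r = R + atom_radius
    serial = 0
    nz = int(round(L / ring_spacing)) + 1
    for iz in range(nz):
        z = -L / 2 + iz * ring_spacing
        n_ring = max(int(math.ceil(2 * math.pi * shell_r / ring_spacing)), 6)
        phase = 0.5 * (iz % 2)  # stagger rings so gaps don't line up
        for ia in range(n_ring):
            t = 2 * math.pi * (ia + phase) / n_ring
            serial += 1
            s.atoms.append(
                Atom(serial, "SH", "C", "CYL", "A", serial,
                     np.array([shell_r * math.cos(t), shell_r * math.sin(t), z]),
                     0.0, atom_radius)
            )
    truth = {"inner_radius_A": R, "length_A": L}
    if bump is not None:
        zb, off, rb = bump
        serial += 1
        s.atoms.append(Atom(serial, "BMP", "C", "BMP", "A", serial,
                            np.array([off, 0.0, zb]), 0.0, rb))
        truth["bump_z_A"] = zb
        truth["bump_min_clearance_A"] = None  # geometry-dependent; see tests
    return Fixture(structure=s, truth=truth)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_fixture(fixture: Fixture, prefix) -> None:
    """Serialize a fixture: PDB + sidecar TSV of charges/radii + truth JSON."""
    prefix = str(prefix)
    write_pdb(fixture.structure, prefix + ".pdb")
    with open(prefix + "_atoms.tsv", "w") as fh:
        fh.write("serial\tname\tresname\tchain\tresnum\tcharge\tradius\n")
        for a in fixture.structure.atoms:
            fh.write(
                f"{a.serial}\t{a.name}\t{a.residue_name}\t{a.chain_id}\t"
                f"{a.residue_number}\t{a.partial_charge:.4f}\t{a.radius:.3f}\n"
            )
    with open(prefix + "_truth.json", "w") as fh:
        json.dump(fixture.truth, fh, indent=2, default=str)
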