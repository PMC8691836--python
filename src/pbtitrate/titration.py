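"""Protonation-microstate Hamiltonian, Monte Carlo titration, and pKa extraction.

The titration Hamiltonian over binary protonation vectors x is

    E(x) = sum_i x_i RT ln10 (pH - pKa_intr,i)
         + sum_{i<j} W_ij gamma_i(x_i) gamma_j(x_j)
         + sum_{His pairs} P (1-x_Ne)(1-x_Nd)

where gamma is each site's charge deviation from its neutral form
(acids: deprotonated -1 / protonated 0; bases: protonated +1 /
deprotonated 0), W is the symmetric matrix of electrostatic interaction
energies between the protonated-minus-deprotonated charge distributions
of site pairs, and the last term excludes the doubly-deprotonated His
tautomer.  Intrinsic pKa values are reference model-compound pKas
shifted by the protein-minus-model difference in desolvation and
background-charge energetics, both from focused linearized
Poisson-Boltzmann solves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .constants import rt, rt_ln10
from .parameters import ParameterSet, default_parameters
from .pbsolver import PBConfig, interaction_energy, solve_focused
from .structure import SiteId, Structure, TitratableSite, assign_parameters

#: Energy penalty (kcal/mol) excluding the doubly-deprotonated His tautomer.
TAUTOMER_PENALTY = 20.0


@dataclass
class SiteEnergetics:
    """Intrinsic pKa vector + site-site interaction matrix: the Hamiltonian."""

    labels: List[str]
    kinds: List[str]  # "acid" | "base" per site
    pka_intrinsic: np.ndarray
    W: np.ndarray  # kcal/mol, symmetric, zero diagonal
    temperature_K: float = 300.0
    tautomer_pairs: List[Tuple[int, int, float]] = field(default_factory=list)
    sites: Optional[List[TitratableSite]] = None
    w_asymmetry: float = 0.0

    def __post_init__(self):
        self.pka_intrinsic = np.asarray(self.pka_intrinsic, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.labels)
        if self.W.shape != (n, n):
            raise ValueError("W shape mismatch")
        if not np.all(np.isfinite(self.pka_intrinsic)):
            raise ValueError("intrinsic pKa values must be finite")
        if np.max(np.abs(self.W - self.W.T)) > 1e-6:
            raise ValueError("W must be symmetric")
        np.fill_diagonal(self.W, 0.0)

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    def gamma_offsets(self) -> np.ndarray:
        """gamma(x) = x + offset: -1 for acids, 0 for bases."""
        return np.array([-1.0 if k == "acid" else 0.0 for k in self.kinds])


@dataclass
class MicrostateEnsemble:
    ph_grid: np.ndarray
    probabilities: np.ndarray  # (n_ph, n_sites), P(protonated)
    energetics: SiteEnergetics
    method: str  # "exact" | "mc"
    mc_sweeps: int = 0
    mc_equilibration: int = 0
    seed: Optional[int] = None
    acceptance_rate: float = float("nan")

    def site_curve(self, i: int) -> np.ndarray:
        return self.probabilities[:, i]


# ---------------------------------------------------------------------------
# Hamiltonian
# ---------------------------------------------------------------------------

def microstate_energy(x: np.ndarray, energetics: SiteEnergetics, ph: float) -> float:
    """Energy (kcal/mol) of one protonation microstate at the given pH."""
    x = np.asarray(x, dtype=float)
    if x.shape != (energetics.n_sites,):
        raise ValueError("protonation vector length mismatch")
    rtl = rt_ln10(energetics.temperature_K)
    e = float(np.dot(x, rtl * (ph - energetics.pka_intrinsic)))
    g = x + energetics.gamma_offsets()
    e += 0.5 * float(g @ energetics.W @ g)
    for i, j, pen in energetics.tautomer_pairs:
        e += pen * (1.0 - x[i]) * (1.0 - x[j])
    return e


def enumerate_exact(
    energetics: SiteEnergetics, ph_grid: Sequence[float]
) -> MicrostateEnsemble:
    """Boltzmann average of x over all 2^N microstates (oracle for the sampler)."""
    n = energetics.n_sites
    if n > 20:
        raise ValueError("exact enumeration limited to 20 sites; use mc_sample")
    ph_grid = np.asarray(ph_grid, dtype=float)
    states = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1).astype(float)
    g = states + energetics.gamma_offsets()[None, :]
    e_int = 0.5 * np.einsum("si,ij,sj->s", g, energetics.W, g)
    for i, j, pen in energetics.tautomer_pairs:
        e_int += pen * (1.0 - states[:, i]) * (1.0 - states[:, j])
    rtl = rt_ln10(energetics.temperature_K)
    beta = 1.0 / rt(energetics.temperature_K)
    probs = np.empty((len(ph_grid), n))
    for k, ph in enumerate(ph_grid):
        e = e_int + states @ (rtl * (ph - energetics.pka_intrinsic))
        w = np.exp(-beta * (e - e.min()))
        w /= w.sum()
        probs[k] = w @ states
    return MicrostateEnsemble(ph_grid=ph_grid, probabilities=probs,
                              energetics=energetics, method="exact")


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

def _mc_kernel_py(field_e, W, goff, tpi, tpj, tpen, pair_i, pair_j, beta,
                  sweeps, equil, seed):
    """Single-pH Metropolis sampler; numba-compiled when available."""
    np.random.seed(seed)
    n = field_e.shape[0]
    x = np.ones(n)
    acc = 0
    prop = 0
    mean = np.zeros(n)

    def delta(i):
        dx = 1.0 - 2.0 * x[i]
        de = dx * field_e[i]
        s = 0.0
        for j in range(n):
            if j != i:
                s += W[i, j] * (x[j] + goff[j])
        de += dx * s
        for t in range(tpi.shape[0]):
            if tpi[t] == i:
                de += -dx * tpen[t] * (1.0 - x[tpj[t]])
            elif tpj[t] == i:
                de += -dx * tpen[t] * (1.0 - x[tpi[t]])
        return de

    for sweep in range(sweeps + equil):
        for i in range(n):
            de = delta(i)
            prop += 1
            if de <= 0.0 or np.random.random() < math.exp(-beta * de):
                x[i] = 1.0 - x[i]
                acc += 1
        for p in range(pair_i.shape[0]):
            i = pair_i[p]
            j = pair_j[p]
            de = delta(i)
            x[i] = 1.0 - x[i]
            de += delta(j)
            x[i] = 1.0 - x[i]  # restore; decide on total
            prop += 1
            if de <= 0.0 or np.random.random() < math.exp(-beta * de):
                x[i] = 1.0 - x[i]
                x[j] = 1.0 - x[j]
                acc += 1
        if sweep >= equil:
            mean += x
    return mean / sweeps, acc, prop


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _mc_kernel = njit(cache=True)(_mc_kernel_py)
except Exception:  # pragma: no cover
    _mc_kernel = _mc_kernel_py


def mc_sample(
    energetics: SiteEnergetics,
    ph_grid: Sequence[float],
    sweeps: int = 100_000,
    equilibration: int = 100,
    seed: int = 0,
    pair_flip_threshold: float = 2.5,
) -> MicrostateEnsemble:
    """Metropolis MC titration: single-site flips plus paired flips for
    strongly coupled pairs (|W| above threshold).  Deterministic per seed."""
    if sweeps <= 0:
        raise ValueError("sweeps must be > 0")
    ph_grid = np.asarray(ph_grid, dtype=float)
    n = energetics.n_sites
    rtl = rt_ln10(energetics.temperature_K)
    beta = 1.0 / rt(energetics.temperature_K)
    goff = energetics.gamma_offsets()
    tp = energetics.tautomer_pairs
    tpi = np.array([t[0] for t in tp], dtype=np.int64)
    tpj = np.array([t[1] for t in tp], dtype=np.int64)
    tpen = np.array([t[2] for t in tp], dtype=np.float64)
    strong = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if abs(energetics.W[i, j]) > pair_flip_threshold
    ] + [(t[0], t[1]) for t in tp]
    pair_i = np.array([p[0] for p in strong], dtype=np.int64)
    pair_j = np.array([p[1] for p in strong], dtype=np.int64)

    probs = np.empty((len(ph_grid), n))
    acc_tot = 0
    prop_tot = 0
    for k, ph in enumerate(ph_grid):
        field_e = rtl * (ph - energetics.pka_intrinsic)
        mean, acc, prop = _mc_kernel(
            field_e, energetics.W, goff, tpi, tpj, tpen, pair_i, pair_j,
            beta, sweeps, equilibration, (seed + 1009 * k) % (2**31 - 1),
        )
        probs[k] = mean
        acc_tot += acc
        prop_tot += prop
    return MicrostateEnsemble(
        ph_grid=ph_grid, probabilities=probs, energetics=energetics,
        method="mc", mc_sweeps=sweeps, mc_equilibration=equilibration,
        seed=seed, acceptance_rate=acc_tot / max(prop_tot, 1),
    )


# ---------------------------------------------------------------------------
# Curve analysis
# ---------------------------------------------------------------------------

def pka_from_curve(
    ensemble: MicrostateEnsemble, site: int, warn: bool = True
) -> Tuple[float, str]:
    """pH at which P(protonated) crosses 0.5, linearly interpolated.

    Returns (pKa, flag); flag is "" for a clean crossing, "extrapolated"
    when the curve never crosses 0.5 in the scanned range, "non-monotone"
    when it crosses more than once (nearest-mid-titration crossing used),
    "undetermined" when the curve sits exactly at 0.5.
    """
    ph = ensemble.ph_grid
    p = ensemble.probabilities[:, site] - 0.5
    if np.all(np.abs(p) < 1e-12):
        return float("nan"), "undetermined"
    crossings = []
    for k in range(len(ph) - 1):
        if p[k] == 0.0:
            crossings.append(float(ph[k]))
        elif p[k] * p[k + 1] < 0:
            t = p[k] / (p[k] - p[k + 1])
            crossings.append(float(ph[k] + t * (ph[k + 1] - ph[k])))
    if p[-1] == 0.0:
        crossings.append(float(ph[-1]))
    if not crossings:
        k = int(np.argmin(np.abs(p)))
        if warn:
            warnings.warn(f"site {site}: titration midpoint outside scanned pH range")
        return float(ph[k]), "extrapolated"
    if len(crossings) == 1:
        return crossings[0], ""
    if warn:
        warnings.warn(f"site {site}: non-monotone titration curve")
    mid = float(ph[int(np.argmin(np.abs(p)))])
    best = min(crossings, key=lambda c: abs(c - mid))
    return best, "non-monotone"


def protonation_pattern(
    ensemble: MicrostateEnsemble, ph: float = 7.0
) -> Dict[str, Tuple[str, float]]:
    """Per-site majority protonation state (with probability) at one pH."""
    k = int(np.argmin(np.abs(ensemble.ph_grid - ph)))
    out: Dict[str, Tuple[str, float]] = {}
    for i, label in enumerate(ensemble.energetics.labels):
        pr = float(ensemble.probabilities[k, i])
        if pr > 0.5:
            out[label] = ("protonated", pr)
        elif pr < 0.5:
            out[label] = ("deprotonated", 1.0 - pr)
        else:
            out[label] = ("undetermined", 0.5)
    return out


# ---------------------------------------------------------------------------
# PB-derived energetics
# ---------------------------------------------------------------------------

def _site_focus_center(s: Structure, site: TitratableSite) -> np.ndarray:
    dq = site.difference_charges()
    idx = list(dq)
    wts = np.abs([dq[i] for i in idx])
    pos = np.array([s.atoms[i].position for i in idx])
    if wts.sum() == 0:
        return pos.mean(axis=0)
    return (pos * wts[:, None]).sum(axis=0) / wts.sum()


def _form_charge_list(s: Structure, site: TitratableSite, protonated: bool):
    return [(s.atoms[i].position, q) for i, q in site.form_charges(protonated).items()]


def _model_compound(s: Structure, site: TitratableSite) -> Tuple[Structure, List[int]]:
    """The site's residue(s) excised with backbone: returns (sub-structure,
    atom-index mapping back to the parent structure)."""
    res_keys = {s.atoms[i].residue_key for i in site.atom_indices()}
    idx_map: List[int] = []
    sub = Structure(provenance={"model_compound": str(site.site_id)})
    for i, a in enumerate(s.atoms):
        if a.residue_key in res_keys:
            sub.atoms.append(
                type(a)(a.serial, a.name, a.element, a.residue_name, a.chain_id,
                        a.residue_number, a.position.copy(), a.partial_charge, a.radius)
            )
            idx_map.append(i)
    return sub, idx_map


@dataclass
class SiteSolutions:
    """Per-site focused PB solutions of the two protonation-form charge sets."""
    protonated: object
    deprotonated: object


def site_deprotonation_shift(
    sp: Structure,
    t: TitratableSite,
    config: PBConfig,
):
    """Protein-minus-model deprotonation energetics of one site.

    ``sp`` must already carry assigned charges for everything except the
    site's own titrating atoms.  Returns (dg_protein, dg_model, sols)
    where each dG is G(deprotonated) - G(protonated) in kcal/mol and
    ``sols`` maps protonation form to its focused protein solution.
    """
    site_atoms = set(t.atom_indices())
    center = _site_focus_center(sp, t)
    bg = [
        (sp.atoms[k].position, sp.atoms[k].partial_charge)
        for k in range(len(sp.atoms))
        if k not in site_atoms and sp.atoms[k].partial_charge != 0.0
    ]

    sols = {}
    g_protein = {}
    for prot in (True, False):
        qlist = _form_charge_list(sp, t, prot)
        sol = solve_focused(sp, qlist, center, config)
        sols[prot] = sol
        g_protein[prot] = 0.5 * interaction_energy(sol, qlist) + interaction_energy(sol, bg)

    model, idx_map = _model_compound(sp, t)
    back_map = {orig: local for local, orig in enumerate(idx_map)}
    model_site_atoms = {back_map[k] for k in site_atoms}
    g_model = {}
    for prot in (True, False):
        qlist = [
            (model.atoms[back_map[k]].position, q)
            for k, q in t.form_charges(prot).items()
        ]
        msol = solve_focused(model, qlist, center, config)
        mbg = [
            (a.position, a.partial_charge)
            for k, a in enumerate(model.atoms)
            if k not in model_site_atoms and a.partial_charge != 0.0
        ]
        g_model[prot] = 0.5 * interaction_energy(msol, qlist) + interaction_energy(msol, mbg)

    dg_protein = g_protein[False] - g_protein[True]
    dg_model = g_model[False] - g_model[True]
    return dg_protein, dg_model, sols


def compute_site_energetics(
    s: Structure,
    sites: Sequence[TitratableSite],
    params: Optional[ParameterSet] = None,
    config: Optional[PBConfig] = None,
    return_solutions: bool = False,
    charge_overrides: Optional[Mapping[int, float]] = None,
):
    """Build the titration Hamiltonian for the free sites of ``s``.

    The structure is assigned with every free site charge-neutral and
    fixed sites in their fixed forms; for each free site the two
    protonation-form charge distributions are solved on focused grids in
    the protein and in the excised model compound (same child-grid
    geometry, so grid self-energies cancel), giving the intrinsic pKa

        pKa_intr = pKa_ref + [dG_deprot(protein) - dG_deprot(model)] / (RT ln10)

    and the interaction matrix W_ij from the difference-distribution
    potentials of site i evaluated on the difference charges of site j.
    """
    params = params or default_parameters()
    config = config or PBConfig()
    sites = list(sites)

    fixed_assignment: Dict[tuple, str] = {}
    for t in sites:
        if t.fixed_state == "fixed-protonated":
            fixed_assignment[t.key] = "protonated"
        elif t.fixed_state == "fixed-deprotonated":
            fixed_assignment[t.key] = "deprotonated"
    sp = assign_parameters(s, params, assignment=fixed_assignment, sites=sites)
    if charge_overrides:
        for k, q in charge_overrides.items():
            sp.atoms[k].partial_charge = q

    free = [t for t in sites if t.fixed_state == "free"]
    n = len(free)
    if n == 0:
        raise ValueError("no free titratable sites")
    rtl = rt_ln10(config.temperature_K)

    pka = np.zeros(n)
    W = np.zeros((n, n))
    solutions: List[SiteSolutions] = []

    site_atoms = [set(t.atom_indices()) for t in free]
    for a_i, a_j in [(i, j) for i in range(n) for j in range(i + 1, n)]:
        if site_atoms[a_i] & site_atoms[a_j]:
            ti, tj = free[a_i], free[a_j]
            if not (ti.site_id == tj.site_id and {ti.site_class, tj.site_class} <=
                    {"His-Ne", "His-Nd"}):
                raise ValueError(
                    f"sites {ti.site_id} and {tj.site_id} share atoms"
                )

    for i, t in enumerate(free):
        dg_protein, dg_model, sols = site_deprotonation_shift(sp, t, config)
        pka[i] = t.reference_pka + (dg_protein - dg_model) / rtl

        for j, u in enumerate(free):
            if j == i or (u.site_id == t.site_id and
                          {t.site_class, u.site_class} <= {"His-Ne", "His-Nd"}):
                continue
            dq_u = [(sp.atoms[k].position, q) for k, q in u.difference_charges().items()]
            W[i, j] = interaction_energy(sols[True], dq_u) - interaction_energy(
                sols[False], dq_u
            )
        solutions.append(SiteSolutions(sols[True], sols[False]))

    asym = float(np.max(np.abs(W - W.T))) if n > 1 else 0.0
    W = 0.5 * (W + W.T)

    tautomer_pairs = []
    for i, t in enumerate(free):
        for j in range(i + 1, n):
            u = free[j]
            if t.site_id == u.site_id and {t.site_class, u.site_class} == {"His-Ne", "His-Nd"}:
                tautomer_pairs.append((i, j, TAUTOMER_PENALTY))

    energetics = SiteEnergetics(
        labels=[t.label for t in free],
        kinds=[params.site_kind(t.site_class) for t in free],
        pka_intrinsic=pka,
        W=W,
        temperature_K=config.temperature_K,
        tautomer_pairs=tautomer_pairs,
        sites=free,
        w_asymmetry=asym,
    )
    if return_solutions:
        return energetics, solutions
    return energetics


def intrinsic_pka(
    site: TitratableSite,
    s: Structure,
    sites: Sequence[TitratableSite],
    params: Optional[ParameterSet] = None,
    config: Optional[PBConfig] = None,
) -> float:
    """Intrinsic pKa of one site (all other sites charge-neutral)."""
    others = [t for t in sites if t is not site]
    frozen = []
    for t in others:
        if t.fixed_state == "free":
            kind = (params or default_parameters()).site_kind(t.site_class)
            state = "fixed-protonated" if kind == "acid" else "fixed-deprotonated"
            t = TitratableSite(
                t.site_id, t.site_class, t.reference_pka, t.charges_protonated,
                t.charges_deprotonated, state, t.atoms_protonated, t.atoms_deprotonated,
            )
        frozen.append(t)
    energetics = compute_site_energetics(s, [site] + frozen, params, config)
    return float(energetics.pka_intrinsic[0])


def interaction_matrix(
    sites: Sequence[TitratableSite],
    s: Structure,
    params: Optional[ParameterSet] = None,
    config: Optional[PBConfig] = None,
) -> np.ndarray:
    """Symmetric matrix of difference-distribution interaction energies."""
    return compute_site_energetics(s, list(sites), params, config).W
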