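"""Per-residue electrostatic contributions to a site's pKa by charge deletion.

The contribution of a perturbing group (another residue's side chain,
the Schiff base, all waters, ...) to a target site's pKa is the change
in the computed pKa when the perturber's atomic charges are set to zero:

    delta = pKa(full) - pKa(charges-deleted)

so a positive charge near an acid contributes a *negative* delta (it
stabilizes the deprotonated form).  In the default fixed-background mode
the other titratable sites keep a prescribed protonation pattern (e.g.
the pH-7 pattern) and only the target re-titrates; because the
linearized PB operator is linear in the source charges, contributions of
disjoint perturbers are then additive to solver precision.  In
equilibrating mode the full multi-site titration is re-run and
non-additive (coupling-mediated) deviations are reported, not failed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .constants import rt_ln10
from .parameters import ParameterSet, default_parameters
from .pbsolver import PBConfig
from .structure import (
    SiteId,
    Structure,
    TitratableSite,
    WATER_NAMES,
    assign_parameters,
)
from .titration import (
    compute_site_energetics,
    enumerate_exact,
    mc_sample,
    pka_from_curve,
    site_deprotonation_shift,
)

Perturber = Union[SiteId, str, TitratableSite]


@dataclass
class ContributionRecord:
    target: str
    perturber: str
    baseline: float  # pKa with all charges present
    perturbed: float  # pKa with the perturber's charges deleted
    delta: float  # baseline - perturbed
    mode: str  # "fixed-background" | "equilibrating"


def resolve_perturber_atoms(
    s: Structure,
    perturber: Perturber,
    params: Optional[ParameterSet] = None,
) -> Tuple[str, Set[int]]:
    """Map a perturber spec to (label, atom-index set).

    A residue key selects that residue's side-chain atoms (backbone
    charges are never deleted); the string ``"H2O"`` selects all water
    atoms as one group; a TitratableSite selects its own atoms (used for
    the Schiff base).  Hetero residues contribute all their atoms.
    """
    params = params or default_parameters()
    if isinstance(perturber, TitratableSite):
        return perturber.label, set(perturber.atom_indices())
    if perturber == "H2O":
        idx = {i for i, a in enumerate(s.atoms) if a.residue_name in WATER_NAMES}
        return "H2O", idx
    chain, resnum, resname = perturber
    idxs = s.residues.get((chain, resnum, resname))
    if not idxs:
        raise ValueError(f"perturber residue {perturber} not found")
    sc_names = params.sidechain_atoms.get(resname)
    if sc_names is None:
        return f"{resname}{resnum}", set(idxs)  # hetero group: all atoms
    idx = {i for i in idxs if s.atoms[i].name in sc_names}
    return f"{resname}{resnum}", idx


def _target_pka(
    s: Structure,
    target: TitratableSite,
    sites: Sequence[TitratableSite],
    params: ParameterSet,
    config: PBConfig,
    background: Mapping[SiteId, str],
    deleted: Set[int],
    mode: str,
    ph_grid: Optional[np.ndarray],
    mc_sweeps: int,
    seed: int,
) -> float:
    overrides = {k: 0.0 for k in deleted}
    if mode == "fixed-background":
        others = []
        for t in sites:
            if t is target:
                continue
            state = t.fixed_state
            if state == "free":
                form = background.get(t.key, background.get(t.site_id))
                if form is None:
                    kind = params.site_kind(t.site_class)
                    form = "protonated" if kind == "acid" else "deprotonated"
                state = f"fixed-{form}"
            others.append(
                TitratableSite(
                    t.site_id, t.site_class, t.reference_pka,
                    t.charges_protonated, t.charges_deprotonated, state,
                    t.atoms_protonated, t.atoms_deprotonated,
                )
            )
        eng = compute_site_energetics(
            s, [target] + others, params, config, charge_overrides=overrides
        )
        return float(eng.pka_intrinsic[0])
    if mode == "equilibrating":
        eng = compute_site_energetics(s, list(sites), params, config,
                                      charge_overrides=overrides)
        grid = ph_grid if ph_grid is not None else np.arange(-15.0, 25.0 + 0.25, 0.5)
        if eng.n_sites <= 12:
            ens = enumerate_exact(eng, grid)
        else:
            ens = mc_sample(eng, grid, sweeps=mc_sweeps, seed=seed)
        i = eng.labels.index(target.label)
        pka, _ = pka_from_curve(ens, i, warn=False)
        return pka
    raise ValueError(f"unknown mode {mode!r}")


def residue_contribution_pka(
    target: TitratableSite,
    perturber: Perturber,
    s: Structure,
    sites: Sequence[TitratableSite],
    params: Optional[ParameterSet] = None,
    config: Optional[PBConfig] = None,
    background: Optional[Mapping[SiteId, str]] = None,
    mode: str = "fixed-background",
    ph_grid: Optional[np.ndarray] = None,
    mc_sweeps: int = 20_000,
    seed: int = 0,
    baseline: Optional[float] = None,
) -> ContributionRecord:
    """Contribution of one perturbing group to the target site's pKa."""
    params = params or default_parameters()
    config = config or PBConfig()
    background = background or {}
    label, atoms = resolve_perturber_atoms(s, perturber, params)
    target_atoms = set(target.atom_indices())
    if atoms & target_atoms:
        raise ValueError(
            f"perturber {label} overlaps the target's titrating atoms"
        )
    if baseline is None:
        baseline = _target_pka(s, target, sites, params, config, background,
                               set(), mode, ph_grid, mc_sweeps, seed)
    perturbed = _target_pka(s, target, sites, params, config, background,
                            atoms, mode, ph_grid, mc_sweeps, seed)
    return ContributionRecord(
        target=target.label, perturber=label, baseline=baseline,
        perturbed=perturbed, delta=baseline - perturbed, mode=mode,
    )


def contribution_table(
    target: TitratableSite,
    perturbers: Sequence[Perturber],
    s: Structure,
    sites: Sequence[TitratableSite],
    **kwargs,
) -> List[ContributionRecord]:
    """One record per perturber, sharing a single baseline computation."""
    params = kwargs.get("params") or default_parameters()
    config = kwargs.get("config") or PBConfig()
    base = _target_pka(
        s, target, sites, params, config, kwargs.get("background") or {},
        set(), kwargs.get("mode", "fixed-background"), kwargs.get("ph_grid"),
        kwargs.get("mc_sweeps", 20_000), kwargs.get("seed", 0),
    )
    records = [
        ContributionRecord(target=target.label, perturber="(baseline)",
                           baseline=base, perturbed=base, delta=0.0,
                           mode=kwargs.get("mode", "fixed-background"))
    ]
    for p in perturbers:
        records.append(
            residue_contribution_pka(target, p, s, sites, baseline=base, **kwargs)
        )
    return records


def contribution_tsv(records: Iterable[ContributionRecord]) -> str:
    lines = ["target\tperturber\tbaseline\tperturbed\tdelta\tmode"]
    for r in records:
        lines.append(
            f"{r.target}\t{r.perturber}\t{r.baseline:.2f}\t{r.perturbed:.2f}\t"
            f"{r.delta:+.2f}\t{r.mode}"
        )
    return "\n".join(lines) + "\n"


def additivity_check(
    target: TitratableSite,
    perturbers: Sequence[Perturber],
    s: Structure,
    sites: Sequence[TitratableSite],
    **kwargs,
) -> Dict:
    """Compare the sum of single-perturber deltas with the joint deletion.

    Perturbers must have mutually exclusive atom sets.  In
    fixed-background mode the two agree to solver tolerance (LPB
    linearity); in equilibrating mode the deviation is reported.
    """
    params = kwargs.get("params") or default_parameters()
    config = kwargs.get("config") or PBConfig()
    mode = kwargs.get("mode", "fixed-background")
    background = kwargs.get("background") or {}
    ph_grid = kwargs.get("ph_grid")
    sweeps = kwargs.get("mc_sweeps", 20_000)
    seed = kwargs.get("seed", 0)

    resolved = [resolve_perturber_atoms(s, p, params) for p in perturbers]
    all_atoms: Set[int] = set()
    for label, atoms in resolved:
        if atoms & all_atoms:
            raise ValueError(f"perturber {label} overlaps another perturber")
        all_atoms |= atoms

    base = _target_pka(s, target, sites, params, config, background, set(),
                       mode, ph_grid, sweeps, seed)
    singles = {}
    for label, atoms in resolved:
        p = _target_pka(s, target, sites, params, config, background, atoms,
                        mode, ph_grid, sweeps, seed)
        singles[label] = base - p
    joint_pka = _target_pka(s, target, sites, params, config, background,
                            all_atoms, mode, ph_grid, sweeps, seed)
    joint = base - joint_pka
    total = sum(singles.values())
    return {
        "target": target.label,
        "mode": mode,
        "baseline_pka": base,
        "individual_deltas": singles,
        "sum_of_deltas": total,
        "joint_delta": joint,
        "deviation": total - joint,
    }
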