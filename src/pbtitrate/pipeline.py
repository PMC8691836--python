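"""End-to-end runs: structure -> sites -> PB -> titration -> report tables.

Every run writes its resolved configuration (and seed) alongside the
outputs, and every output file carries a header with the tool version,
a hash of the resolved config, and the seed, so reruns are bit-for-bit
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from .channel import compare_profiles, constriction, profile_tsv, radius_profile
from .decomposition import contribution_table, contribution_tsv
from .hydrogens import place_hydrogens
from .parameters import default_parameters
from .pbsolver import PBConfig
from .spectral import format_shift_table, read_gap_table, records_from_frame, shift_table
from .structure import (
    Structure,
    apply_variants,
    enumerate_titratable_sites,
    read_pdb,
    read_variant_tsv,
    site_inventory_table,
)
from .titration import (
    compute_site_energetics,
    enumerate_exact,
    mc_sample,
    pka_from_curve,
    protonation_pattern,
)

log = logging.getLogger("pbtitrate")


@dataclass
class RunConfig:
    """Run settings; defaults are the study conditions (eps 4/80, 100 mM,
    300 K, pH 7, focusing 2.5/1.0/0.3 A)."""

    pdb: Optional[str] = None
    chain: Optional[str] = None
    variants: Optional[str] = None  # TSV path
    waters: str = "implicit"  # implicit | explicit
    eps_in: float = 4.0
    eps_out: float = 80.0
    ionic_strength_mM: float = 100.0
    temperature_K: float = 300.0
    focusing_spacings_A: Tuple[float, ...] = (2.5, 1.0, 0.3)
    stern_A: float = 2.0
    tol: float = 1e-8
    ph_min: float = -15.0
    ph_max: float = 25.0
    ph_step: float = 0.5
    ph_report: float = 7.0
    sweeps: int = 100_000
    equilibration: int = 100
    pair_flip_threshold: float = 2.5
    seed: int = 0
    exact_max_sites: int = 12
    outdir: str = "pbtitrate_out"

    def pb(self) -> PBConfig:
        return PBConfig(
            eps_in=self.eps_in,
            eps_out=self.eps_out,
            ionic_strength_M=self.ionic_strength_mM / 1000.0,
            temperature_K=self.temperature_K,
            focusing_spacings=tuple(self.focusing_spacings_A),
            stern_A=self.stern_A,
            tol=self.tol,
        )

    def ph_grid(self) -> np.ndarray:
        return np.arange(self.ph_min, self.ph_max + self.ph_step / 2, self.ph_step)

    def resolved(self) -> Dict:
        return asdict(self)

    def config_hash(self) -> str:
        resolved = self.resolved()
        resolved.pop("outdir", None)  # where results land is not a setting
        blob = json.dumps(resolved, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _header(config: RunConfig) -> str:
    return (
        f"# pbtitrate {__version__}\tconfig={config.config_hash()}\t"
        f"seed={config.seed}\n"
    )


def _write(path: Path, config: RunConfig, body: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(_header(config) + body)


def load_structure(config: RunConfig) -> Structure:
    if config.pdb is None:
        raise ValueError("config.pdb is required")
    s = read_pdb(config.pdb, chain=config.chain,
                 keep_waters=config.waters == "explicit")
    if config.variants:
        s = apply_variants(s, read_variant_tsv(config.variants))
    return place_hydrogens(s)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1f s", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run_titration(
    config: RunConfig,
    structure: Optional[Structure] = None,
    sites: Optional[List] = None,
) -> Dict:
    """Full titration run; returns a summary dict and writes TSV tables.

    ``structure``/``sites`` may be supplied directly (synthetic fixtures);
    otherwise they are loaded from the configured PDB.
    """
    params = default_parameters()
    outdir = Path(config.outdir)
    if structure is None:
        structure = _stage("load")(load_structure)(config)
    if sites is None:
        sites = _stage("sites")(enumerate_titratable_sites)(structure, params)
    _write(outdir / "sites.tsv", config, site_inventory_table(sites))

    energetics = _stage("energetics")(compute_site_energetics)(
        structure, sites, params, config.pb()
    )
    grid = config.ph_grid()
    if energetics.n_sites <= config.exact_max_sites:
        ensemble = _stage("titration")(enumerate_exact)(energetics, grid)
    else:
        ensemble = _stage("titration")(mc_sample)(
            energetics, grid, sweeps=config.sweeps,
            equilibration=config.equilibration, seed=config.seed,
            pair_flip_threshold=config.pair_flip_threshold,
        )

    curves = ["pH\tsite\tprob_protonated"]
    for k, ph in enumerate(grid):
        for i, lab in enumerate(energetics.labels):
            curves.append(f"{ph:.2f}\t{lab}\t{ensemble.probabilities[k, i]:.6f}")
    _write(outdir / "titration_curves.tsv", config, "\n".join(curves) + "\n")

    pkas = {}
    rows = ["site\tclass\tpka_intrinsic\tpka\tflag"]
    for i, lab in enumerate(energetics.labels):
        pka, flag = pka_from_curve(ensemble, i, warn=False)
        pkas[lab] = (pka, flag)
        cls = energetics.sites[i].site_class if energetics.sites else energetics.kinds[i]
        rows.append(f"{lab}\t{cls}\t{energetics.pka_intrinsic[i]:.2f}\t{pka:.2f}\t{flag}")
    _write(outdir / "pka.tsv", config, "\n".join(rows) + "\n")

    pattern = protonation_pattern(ensemble, config.ph_report)
    rows = ["site\tstate\tprobability"]
    for lab, (state, pr) in pattern.items():
        rows.append(f"{lab}\t{state}\t{pr:.3f}")
    _write(outdir / "pattern.tsv", config, "\n".join(rows) + "\n")

    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh)
    return {
        "energetics": energetics,
        "ensemble": ensemble,
        "pka": pkas,
        "pattern": pattern,
    }


def run_contributions(
    config: RunConfig,
    target_label: str,
    perturbers: Sequence,
    structure: Optional[Structure] = None,
    sites: Optional[List] = None,
    background: Optional[Dict] = None,
) -> List:
    params = default_parameters()
    if structure is None:
        structure = load_structure(config)
    if sites is None:
        sites = enumerate_titratable_sites(structure, params)
    target = next((t for t in sites if t.label == target_label), None)
    if target is None:
        raise ValueError(f"target site {target_label!r} not found; have "
                         f"{[t.label for t in sites]}")
    records = contribution_table(
        target, perturbers, structure, sites,
        params=params, config=config.pb(), background=background,
    )
    _write(Path(config.outdir) / "contributions.tsv", config, contribution_tsv(records))
    return records


def run_spectra(config: RunConfig, gap_table_path, reference_variant: str):
    """Table-4-shaped wavelength/shift report from a gap-energy table."""
    df = read_gap_table(gap_table_path)
    table = shift_table(records_from_frame(df), reference_variant)
    outdir = Path(config.outdir)
    _write(outdir / "wavelengths.tsv", config,
           table.to_csv(sep="\t", index=False, float_format="%.3f"))
    _write(outdir / "wavelengths_report.tsv", config, format_shift_table(table))
    return table


def run_channel(
    config: RunConfig,
    start,
    end,
    structure: Optional[Structure] = None,
    compare_with: Optional[Structure] = None,
    step: float = 0.5,
):
    from .structure import assign_parameters

    if structure is None:
        structure = load_structure(config)
    if not np.any(structure.radii() > 0):
        structure = assign_parameters(structure)
    profile = radius_profile(structure, start, end, step=step)
    outdir = Path(config.outdir)
    _write(outdir / "channel_profile.tsv", config, profile_tsv(profile))
    result = {"profile": profile, "constriction": constriction(profile)}
    if compare_with is not None:
        other = radius_profile(compare_with, start, end, step=step)
        df = compare_profiles(profile, other)
        _write(outdir / "channel_comparison.tsv", config,
               df.to_csv(sep="\t", index=False, float_format="%.3f"))
        result["comparison"] = df
    return result
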