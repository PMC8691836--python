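"""Empirical absorption-energy conversion and spectral-shift bookkeeping.

Retinal-protein absorption maxima correlate tightly with the
HOMO-LUMO orbital gap (dE) or the lowest TD-DFT excitation energy (E) of
the chromophore.  Two affine calibrations convert those quantum-chemistry
outputs (supplied as input tables; this package computes neither) to an
absorption energy in eV:

    E_abs = 0.842 dE_HOMO-LUMO + 0.408        (gap channel)
    E_abs = 1.455 E_TD-DFT    - 1.056         (excitation channel)

with lambda_max = hc / E_abs (hc = 1239.84193 eV nm).  Report tables
average wavelengths over MD conformers per variant and print shifts
against a named reference variant; per-residue wavelength contributions
come from the gap shift on deleting one side chain's atomic charges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .constants import HC_EV_NM

GAP_SLOPE, GAP_OFFSET = 0.842, 0.408
TDDFT_SLOPE, TDDFT_OFFSET = 1.455, -1.056


@dataclass
class SpectralRecord:
    variant: str
    conformer: str
    gap_eV: float
    tddft_eV: Optional[float] = None

    @property
    def eabs_gap(self) -> float:
        return eabs_from_gap(self.gap_eV)

    @property
    def lambda_gap_nm(self) -> float:
        return wavelength(self.eabs_gap)


def eabs_from_gap(gap_eV: float) -> float:
    """Absorption energy (eV) from the HOMO-LUMO gap."""
    if gap_eV <= 0:
        raise ValueError(f"HOMO-LUMO gap must be > 0 eV, got {gap_eV}")
    return GAP_SLOPE * gap_eV + GAP_OFFSET


def eabs_from_tddft(exc_eV: float) -> float:
    """Absorption energy (eV) from the TD-DFT excitation energy."""
    if TDDFT_SLOPE * exc_eV + TDDFT_OFFSET <= 0:
        raise ValueError(
            f"TD-DFT excitation energy {exc_eV} eV maps to a non-positive "
            f"absorption energy (domain: > {-TDDFT_OFFSET / TDDFT_SLOPE:.4f} eV)"
        )
    return TDDFT_SLOPE * exc_eV + TDDFT_OFFSET


def wavelength(e_eV: float) -> float:
    """Photon wavelength in nm for an energy in eV."""
    if e_eV <= 0:
        raise ValueError(f"energy must be > 0 eV, got {e_eV}")
    return HC_EV_NM / e_eV


def gap_for_wavelength(lambda_nm: float) -> float:
    """Invert the gap calibration: the gap whose absorption is lambda_nm."""
    return (HC_EV_NM / lambda_nm - GAP_OFFSET) / GAP_SLOPE


def read_gap_table(path) -> pd.DataFrame:
    """TSV with columns: variant, conformer, gap_eV [, tddft_eV]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"variant", "conformer", "gap_eV"}
    if not required <= set(df.columns):
        raise ValueError(f"gap table needs columns {sorted(required)}")
    return df


def records_from_frame(df: pd.DataFrame) -> List[SpectralRecord]:
    return [
        SpectralRecord(
            variant=str(r.variant),
            conformer=str(r.conformer),
            gap_eV=float(r.gap_eV),
            tddft_eV=float(r.tddft_eV) if "tddft_eV" in df.columns and pd.notna(r.tddft_eV) else None,
        )
        for r in df.itertuples()
    ]


def shift_table(
    records: Sequence[SpectralRecord], reference_variant: str
) -> pd.DataFrame:
    """Per-variant conformer-averaged wavelengths and shifts vs reference.

    Wavelengths are averaged (not energies; the choice matters at the
    sub-nm level only) per variant over conformers; the TD-DFT channel is
    reported alongside when excitation energies are present.
    """
    variants: Dict[str, Dict[str, List[float]]] = {}
    for r in records:
        d = variants.setdefault(r.variant, {"gap": [], "tddft": []})
        d["gap"].append(wavelength(eabs_from_gap(r.gap_eV)))
        if r.tddft_eV is not None:
            d["tddft"].append(wavelength(eabs_from_tddft(r.tddft_eV)))
    if reference_variant not in variants:
        raise ValueError(f"unknown reference variant {reference_variant!r}")
    rows = []
    for v, d in variants.items():
        rows.append(
            {
                "variant": v,
                "n_conformers": len(d["gap"]),
                "lambda_max_nm": sum(d["gap"]) / len(d["gap"]),
                "lambda_max_tddft_nm": (
                    sum(d["tddft"]) / len(d["tddft"]) if d["tddft"] else float("nan")
                ),
            }
        )
    df = pd.DataFrame(rows)
    ref = df.loc[df.variant == reference_variant].iloc[0]
    df["dlambda_nm"] = df["lambda_max_nm"] - ref["lambda_max_nm"]
    df["dlambda_tddft_nm"] = df["lambda_max_tddft_nm"] - ref["lambda_max_tddft_nm"]
    return df


def format_shift_table(df: pd.DataFrame) -> str:
    """Report-style TSV with wavelengths rounded to integer nm and the
    TD-DFT channel in parentheses."""
    lines = ["variant\tlambda_max_nm\tdlambda_nm"]
    for r in df.itertuples():
        if pd.notna(r.lambda_max_tddft_nm):
            lam = f"{r.lambda_max_nm:.0f}({r.lambda_max_tddft_nm:.0f})"
            dl = f"{r.dlambda_nm:+.0f}({r.dlambda_tddft_nm:+.0f})"
        else:
            lam = f"{r.lambda_max_nm:.0f}"
            dl = f"{r.dlambda_nm:+.0f}"
        lines.append(f"{r.variant}\t{lam}\t{dl}")
    return "\n".join(lines) + "\n"


def residue_contribution_wavelength(gap_full_eV: float, gap_deleted_eV: float) -> float:
    """Wavelength contribution (nm) of one side chain's charges.

    Computed from the gap with all charges present minus the gap with
    the side chain's charges removed: positive when the charges red-shift
    the absorption.
    """
    return wavelength(eabs_from_gap(gap_full_eV)) - wavelength(eabs_from_gap(gap_deleted_eV))


def wavelength_contribution_table(
    rows: Sequence[tuple], total_label: str = "Total"
) -> pd.DataFrame:
    """Assemble a per-residue wavelength-contribution table.

    ``rows``: (perturber_label, gap_full_eV, gap_deleted_eV) triples; a
    Total row sums the contributions.
    """
    out = []
    for label, g_full, g_del in rows:
        out.append(
            {
                "perturber": label,
                "gap_full_eV": g_full,
                "gap_deleted_eV": g_del,
                "contribution_nm": residue_contribution_wavelength(g_full, g_del),
            }
        )
    df = pd.DataFrame(out)
    total = {
        "perturber": total_label,
        "gap_full_eV": float("nan"),
        "gap_deleted_eV": float("nan"),
        "contribution_nm": df["contribution_nm"].sum(),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
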