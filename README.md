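# pbtitrate

Continuum-electrostatics protonation analysis for membrane proteins,
built around the question of which acidic residue serves as the
counterion of a protonated retinal Schiff base. In the anion
channelrhodopsin GtACR1, two candidate acids flank the Schiff base —
an aspartate 3.2 Å away and a glutamate at 5.3 Å — and their
protonation states decide how the channel tunes its absorption and
gates anion flow. `pbtitrate` re-implements the computational workflow
used to settle such questions as a tested, reusable library and CLI:

- **Finite-difference linearized Poisson–Boltzmann (LPB) solver** with
  three-step grid focusing (2.5 → 1.0 → 0.3 Å), harmonic-mean boundary
  dielectrics, Debye–Hückel screening and screened-Coulomb boundary
  conditions.
- **Titration engine**: intrinsic pKa values from protein-vs-model-compound
  LPB energetics, a symmetric site–site interaction matrix `W`,
  Metropolis Monte Carlo sampling of protonation microstates (with exact
  enumeration as the oracle for ≤ 20 sites), titration curves, and
  half-titration pKa extraction.
- **Charge-deletion decomposition** of a site's pKa into per-residue
  electrostatic contributions.
- **Spectral bookkeeping**: empirical conversion of HOMO–LUMO gaps and
  TD-DFT excitation energies (supplied as input tables) to absorption
  wavelengths, conformer-averaged mutant shift tables, and per-residue
  wavelength contributions.
- **Pore-radius profiling** along a channel axis with constriction
  detection.
- **Synthetic fixtures** with closed-form ground truth (Born ions,
  charge pairs, titration toys, a mock Schiff-base/diacid system,
  cylindrical pores), so every stage is testable without downloads.

## The model

Protonation microstates `x ∈ {0,1}^N` of the titratable sites are
sampled from the Hamiltonian

```
E(x) = Σ_i x_i·RT·ln10·(pH − pKa_intr,i)  +  Σ_{i<j} W_ij·γ_i(x_i)·γ_j(x_j)
```

where `γ` is each site's charge deviation from its neutral form (acids:
deprotonated −1; bases: protonated +1) and `W_ij` is the LPB interaction
energy between the protonated-minus-deprotonated charge distributions of
sites `i` and `j`. The intrinsic pKa shifts a measured model-compound
reference by the protein-minus-model difference in deprotonation
energetics (desolvation + background charges):

```
pKa_intr = pKa_ref + [ΔG_deprot(protein) − ΔG_deprot(model)] / (RT·ln10)
```

Defaults are ε = 4 inside the protein / 80 in water, 300 K, pH 7.0,
100 mM ionic strength. Reference pKa values: Arg 12.0, Asp 4.0, Cys 9.5,
Glu 4.4, Lys 10.4, Tyr 9.6, His Nε 7.0 / Nδ 6.6. The absorption-energy
calibrations are `E_abs = 0.842·ΔE_HOMO-LUMO + 0.408` and
`E_abs = 1.455·E_TD-DFT − 1.056` (eV), with `λ = 1239.84193/E_abs` nm.

## Worked example

The mock counterion system places a fixed +1 "Schiff base" group inside
a low-dielectric sphere with two titratable acids at 3.2 Å (Asp-like,
reference pKa 4.0) and 5.3 Å (Glu-like, 4.4):

```python
import numpy as np
from pbtitrate import (PBConfig, compute_site_energetics, enumerate_exact,
                       pka_from_curve, protonation_pattern)
from pbtitrate.synthetic import make_mock_schiffbase

fx = make_mock_schiffbase()          # +1 charge, acids at 3.2 / 5.3 A
eng = compute_site_energetics(fx.structure, fx.sites, config=PBConfig())
ens = enumerate_exact(eng, np.arange(-15, 25.5, 0.5))
for i, label in enumerate(eng.labels):
    pka, _ = pka_from_curve(ens, i)
    print(f"{label}: intrinsic pKa {eng.pka_intrinsic[i]:.1f}, titration pKa {pka:.1f}")
print("coupling W =", f"{eng.W[0,1]:.1f} kcal/mol")
for site, (state, p) in protonation_pattern(ens, ph=7.0).items():
    print(f"pH 7: {site} -> {state} ({p:.3f})")
```

prints

```
NEA2:A-Asp: intrinsic pKa 2.4, titration pKa 2.4
FAA3:A-Glu: intrinsic pKa 6.0, titration pKa 12.1
coupling W = 8.3 kcal/mol
pH 7: NEA2:A-Asp -> deprotonated (1.000)
pH 7: FAA3:A-Glu -> protonated (1.000)
```

The near acid is strongly stabilized in its ionized form by the +1
charge (intrinsic pKa pushed below its 4.0 reference despite the burial
penalty) and stays deprotonated at pH 7. The far acid alone would also
titrate below 7, but once the near acid is ionized their +8.3 kcal/mol
repulsive coupling raises its effective pKa to ~12 — one counterion,
not two, exactly the behavior expected at a protonated Schiff base.

The same machinery runs on real structures from the shell, e.g.

```bash
pbtitrate titrate protein.pdb --chain A --outdir out/     # pKa + pattern tables
pbtitrate contrib protein.pdb ASP234:A-Asp A:238:LYS H2O  # charge-deletion table
pbtitrate spectra gaps.tsv --reference wild-type          # mutant shift table
pbtitrate channel protein.pdb --start x y z --end x y z   # pore-radius profile
pbtitrate synth mock_schiffbase                           # emit fixtures
```

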