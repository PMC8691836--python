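# Methods

## Scope and model

`pbtitrate` computes equilibrium protonation states of titratable
groups in a rigid protein structure from continuum electrostatics, plus
three satellite analyses that together cover the standard workflow for
retinal-protein counterion questions: per-residue pKa decomposition,
absorption-wavelength bookkeeping, and pore-radius profiling. The
physical model is the usual two-dielectric continuum: the protein is a
low-dielectric cavity (ε_in = 4 by default) defined by the van der
Waals union of its atom spheres, embedded in high-dielectric solvent
(ε_out = 80) with a 1:1 electrolyte (100 mM, 300 K) treated at the
linearized Poisson–Boltzmann (LPB) level. Conformational relaxation is
outside the model: heavy atoms never move, and hydrogen positions come
from geometric templates, not an energy minimization.

## LPB solver

The equation `∇·(ε∇φ) − ε_out κ² φ = −4πC ρ` is discretized with a
7-point finite-difference stencil on uniform Cartesian grids
(potentials in kcal/(mol·e), C = 332.06 kcal·Å/mol·e²). Numerical
choices that matter:

- **Dielectric boundary.** Edge dielectrics are harmonic means weighted
  by the fraction of each edge inside the solute, computed from a
  signed-distance grid (distance to the nearest atom surface) by linear
  interpolation of the zero crossing. The harmonic average is exact for
  a 1-D layered medium and keeps Born-energy discretization error near
  1% at 0.3 Å spacing. The surface is the plain sphere union — no
  reentrant (molecular) surface; this is a documented simplification
  and the boundary builder is swappable.
- **Ion screening.** κ² is zero inside the solute and within a 2.0 Å
  Stern layer of its surface, else set from the Debye expression
  (λ_D ≈ 9.7 Å at the defaults).
- **Charge assignment.** Point charges are spread onto 5³ nodes with a
  Gaussian of σ = 0.8 grid spacings. The lattice Green's function of an
  on-node point source deviates ~4% from Coulomb at three spacings; the
  Gaussian-resolved source stays within ~2% there, while its far-field
  correction (an erf factor) is < 0.1% beyond 3 h. All energy
  differences are taken between solves with identical grids and
  spreading, so the residual self-energy cancels.
- **Boundary conditions and focusing.** Outer faces carry the
  screened-Coulomb superposition of the source charges; focused child
  grids (2.5 → 1.0 → 0.3 Å, child boxes 24 and 9.6 Å wide centered on
  the site of interest) take boundary values interpolated from the
  parent solution. The coarsest grid spans the molecule plus a 15 Å
  margin. Multi-level evaluation of a potential at a point uses the
  finest grid containing it, falling back to the parent within two
  spacings of a child boundary, where the interpolated-boundary error
  concentrates.
- **Linear solve.** Jacobi-preconditioned conjugate gradients on the
  symmetric positive-definite system, relative residual 1e-8, warm
  started from the analytic screened-Coulomb guess. Any method meeting
  the residual tolerance is contractually equivalent.

## Titration energetics

Each titratable site carries two charge forms differing by exactly one
proton. The intrinsic pKa is the reference model-compound pKa shifted
by the protein-minus-model difference of the deprotonation energy,

    pKa_intr = pKa_ref + [ΔG_deprot(protein) − ΔG_deprot(model)] / (RT ln10),

where each ΔG sums the form's reaction-field self-energy and its
interaction with all background charges, computed with every other free
site in its charge-neutral form. The model compound is the site's
residue(s) excised with backbone into pure solvent, solved on child
grids with identical geometry relative to the site, so grid artifacts
cancel; for an isolated model compound the two environments are
identical and the recovery of the reference pKa is exact by
construction (this is a test, not an assumption). The interaction
matrix `W_ij` contracts the potential of site *i*'s
protonated-minus-deprotonated charge distribution with site *j*'s
difference charges; it is symmetrized (the raw asymmetry, a focused-grid
interpolation effect, is recorded on the result) and its diagonal is
zero.

Protonated acids are represented without an explicit carboxyl hydrogen
— the proton's charge is smeared over the carboxylate — so a single
hydrogen-placement pass with all titratable groups ionized serves every
protonation form. Histidine is two coupled sub-sites (Nε ref 7.0, Nδ
6.6); the doubly-deprotonated tautomer is excluded by an explicit
+20 kcal/mol pair penalty in the Hamiltonian rather than through `W`,
which stays purely electrostatic. With the partner nitrogen held
protonated each sub-site titrates at its reference in the isolated
limit; with both free the neutral tautomer equilibrium keeps the
majority proton on Nε, which is the physically expected behavior.
Chain termini are titratable by default (N-term 8.0, C-term 3.8,
standard model-compound values). The retinal Schiff base is one
composite site (retinal + conserved lysine), fixed protonated by
default.

## Microstate sampling

The Hamiltonian is `E(x) = Σ x_i RT ln10 (pH − pKa_intr,i) +
Σ_{i<j} W_ij γ_i γ_j` with γ the deviation from the neutral form. Exact
enumeration (≤ 20 sites) is the oracle; the Metropolis sampler performs
one single-site sweep plus paired flips for strongly coupled pairs
(|W| > 2.5 kcal/mol, and all His tautomer pairs) per sweep, with 100
equilibration and 10⁵ production sweeps per pH point by default. The
kernel is numba-compiled when numba is importable, with an identical
pure-Python fallback; runs are deterministic per seed within one
backend. pKa values are half-titration points, linearly interpolated on
the pH grid (default −15 to +25 in 0.5 steps — wide because coupled
systems can shift midpoints by many units); curves that never cross 0.5
are flagged `extrapolated`, multiple crossings `non-monotone`, and a
curve pinned at exactly 0.5 reports `undetermined` rather than rounding.

## Charge-deletion decomposition

The contribution of a perturbing group to a target's pKa is
`pKa(full) − pKa(perturber side-chain charges zeroed)`; backbone
charges are never deleted with a side chain, all explicit waters form
one "H2O" group, and deletion changes charges only (the dielectric
cavity is unchanged). In the default fixed-background mode the other
sites keep a prescribed pattern (e.g. the pH-7 state) and only the
target re-titrates; LPB linearity then makes disjoint contributions
exactly additive, which is asserted to < 0.05 pKa units. An
equilibrating mode re-runs the full titration and reports (not fails)
coupling-mediated non-additivity.

## Spectral layer

The package computes no quantum chemistry: HOMO–LUMO gaps and TD-DFT
excitation energies arrive as TSV input (`variant, conformer, gap_eV
[, tddft_eV]`). The two affine calibrations (slopes 0.842 / 1.455,
offsets +0.408 / −1.056 eV) and hc = 1239.84193 eV·nm are fixed
constants; their provenance (a regression over rhodopsin variants) is
not re-fit here. Mutant tables average *wavelengths* over conformers
(averaging energies first differs only at the sub-nm level for the
spreads involved); report tables round to integer nm while full
precision is kept internally. Per-residue wavelength contributions use
the gap shift upon deleting one side chain's charges through the same
calibration.

## Pore profiling

The profiler samples a straight axis in 0.5 Å steps; at each step the
probe center moves within the normal plane (0.25 Å polar grid, 5 Å
lateral cap) to the largest-clearance position, and the radius is the
distance to the nearest atom surface, capped at 10 Å. This is a greedy
sphere-probe approximation of tunnel analysis: it localizes
constrictions (e.g. a side chain swinging into an open pore) but does
not do Voronoi tunnel clustering, branch finding, or curved-path
optimization.

## Synthetic data

The generators produce the study conditions for every testable claim:
Born ions and charge pairs with closed-form energies; titration toys
whose site separations are back-solved from Coulomb's law so the PB
pipeline must reproduce a requested Hamiltonian (infeasible couplings —
attraction between like-charged sites, or unembeddable distance
matrices — raise errors naming the offending pair); a mock Schiff-base
system with a fixed +1 group and two acids at 3.2 / 5.3 Å (references
4.0 / 4.4, acid–acid distance 4.5 Å, all inside a 12 Å sphere of
neutral filler atoms at 2.8 Å spacing — the sphere radius and packing
are package choices, stated once and not tuned); and cylindrical pore
shells. Fixture truths come from closed forms or enumeration only,
never from the code under test. What the fixtures do *not* emulate:
conformational ensembles, lipid bilayers, explicit-water networks, or
real side-chain sterics — passing tests demonstrate the correctness of
the electrostatics/sampling machinery, not the accuracy of any
particular protein prediction.

## Parameter tables

The bundled charge set is a compact polar-hydrogen set authored for
this package (nonpolar hydrogens implicit, localized polar charges),
satisfying two hard invariants checked in the tests: every neutral form
sums to zero and every site's protonated-minus-deprotonated difference
is exactly +1. Radii are per-element van der Waals values (C 1.90,
N 1.625, O 1.48, S 1.85, H 1.00 Å). Continuum pKa shifts computed here
depend on these tables quantitatively, so `ParameterSet` is a swappable
value object — a force-field-derived set can be dropped in without
touching the machinery. Crystal waters can be kept explicit or dropped
(implicit treatment is the default for titration runs); explicit waters
lacking hydrogens are treated as neutral.

## Problem sizes and tolerances

The validation suite runs at desk scale: Born/Coulomb/Debye checks on
41–61³ grids, 20 random coupled systems of 2–10 sites × ~13 pH points ×
10⁵ MC sweeps, ten single-residue recovery titrations, the 201-atom
mock Schiff-base system, and ≤ 100-atom pore fixtures — a few minutes
on one CPU in total. Asserted tolerances: 2% (Born, Coulomb), 3%
(Debye), 0.01 (MC vs exact probability), ±0.05 pH (reference
recovery), 0.05 pKa (additivity), 0.2 Å (cylinder radius).

## Known limitations

Rigid heavy atoms; template (not minimized) hydrogens; sphere-union
dielectric boundary; no membrane slab or nonlinear PB; single-structure
pKas (conformational averaging must be done by running per conformer
and tabulating); the in-silico mutation helper only supports
atom-removing substitutions (Asp→Asn, Glu→Gln, Glu→Asp) — anything
requiring new heavy atoms needs an externally built mutant structure;
full-protein absorption wavelengths require external QM inputs by
design.
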