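"""Physical constants and unit conversions used throughout the package.

Internal unit system: lengths in Angstrom, charges in units of the
elementary charge e, energies in kcal/mol, potentials in kcal/(mol*e).
"""

import math

#: Coulomb constant e^2/(4 pi eps0), kcal*A/(mol*e^2).
COULOMB_KCAL = 332.06

#: Gas constant, kcal/(mol*K).
R_KCAL = 1.9872041e-3

#: Planck * speed of light, eV*nm (energy <-> wavelength conversion).
HC_EV_NM = 1239.84193

#: Avogadro's number scaled to particles per A^3 per (mol/L).
_MOLAR_TO_PER_A3 = 6.02214076e23 / 1.0e27

LN10 = math.log(10.0)


def rt(temperature_k: float) -> float:
    """Thermal energy RT in kcal/mol."""
    return R_KCAL * temperature_k


def rt_ln10(temperature_k: float) -> float:
    """RT*ln(10) in kcal/mol: the free-energy cost of one pH unit.

    At 300 K this is ~1.373 kcal/mol.
    """
    return rt(temperature_k) * LN10


def kappa2(ionic_strength_molar: float, eps_out: float, temperature_k: float) -> float:
    """Squared inverse Debye length, A^-2, for a 1:1 electrolyte.

    kappa^2 = 8 pi C I N_A / (eps_out RT); at 100 mM, eps 80, 300 K the
    Debye length 1/kappa is ~9.7 A.
    """
    if ionic_strength_molar < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength_molar == 0.0:
        return 0.0
    return (
        8.0
        * math.pi
        * COULOMB_KCAL
        * ionic_strength_molar
        * _MOLAR_TO_PER_A3
        / (eps_out * rt(temperature_k))
    )
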