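"""Physical constants (CODATA 2018) and unit conversions.

Internal unit policy: lengths in Å, energies in kcal/mol, temperatures in K,
entropies in cal/(mol·K).  All conversions happen here or at I/O boundaries —
never silently inside an algorithm.
"""

from scipy import constants as _c

#: Boltzmann constant, J/K
K_B = _c.k
#: Planck constant, J·s
H_PLANCK = _c.h
#: Avogadro constant, 1/mol
N_A = _c.N_A
#: Speed of light, m/s
C_LIGHT = _c.c
#: Molar gas constant, J/(mol·K)
R_J = _c.R

#: Thermochemical calorie, J
CAL = _c.calorie
#: Molar gas constant, kcal/(mol·K)
R_KCAL = R_J / (CAL * 1000.0)
#: Molar gas constant, cal/(mol·K)
R_CAL = R_J / CAL

#: 1 cm⁻¹ of photon energy, in kcal/mol (≈ 2.85914e-3)
CM1_TO_KCAL = H_PLANCK * C_LIGHT * 100.0 * N_A / (CAL * 1000.0)
#: 1 hartree in kcal/mol (≈ 627.5095)
HARTREE_TO_KCAL = _c.value("Hartree energy") * N_A / (CAL * 1000.0)

#: Standard pressure for ideal-gas translational terms, Pa (1 atm)
P_STANDARD = _c.atm

#: Atomic mass unit, kg
AMU = _c.atomic_mass


def eyring_prefactor(temperature: float) -> float:
    """k_B·T/h in s⁻¹ — the universal TST frequency factor."""
    return K_B * temperature / H_PLANCK
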