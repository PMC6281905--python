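"""Ideal-gas rigid-rotor harmonic-oscillator (RRHO) thermochemistry.

Converts electronic energies plus harmonic wavenumbers into Gibbs free
energies.  The statistical-mechanics standard state is the ideal gas at 1 atm;
the transition-state-theory standard-state factor c° is applied in the
kinetics module, not here.  Imaginary modes are encoded as negative
wavenumbers; a transition state must carry exactly one, and it is excluded
from every statistical sum.

No quasi-harmonic floor is applied to low frequencies: the harmonic partition
function is evaluated as-is, which is the simplest defensible choice when the
upstream electronic-structure protocol did not specify one.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import AMU, CM1_TO_KCAL, C_LIGHT, H_PLANCK, K_B, N_A, P_STANDARD, R_CAL, R_KCAL
from .errors import InvalidTransitionStateError
from .io_structures import Geometry

__all__ = [
    "FrequencySet",
    "ThermoResult",
    "zero_point_energy",
    "rrho_corrections",
    "activation_free_energy",
]

_LINEAR_MOMENT_TOL = 1e-6  # amu·Å² — below this a principal moment counts as zero


@dataclass(frozen=True)
class FrequencySet:
    """Harmonic wavenumbers in cm⁻¹; negative entries encode imaginary modes."""

    wavenumbers: tuple[float, ...]
    is_ts: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavenumbers", tuple(float(w) for w in self.wavenumbers))
        n_imag = sum(1 for w in self.wavenumbers if w < 0)
        if self.is_ts and n_imag != 1:
            raise InvalidTransitionStateError(
                f"a transition state needs exactly 1 imaginary mode, found {n_imag}"
            )
        if not self.is_ts and n_imag != 0:
            raise InvalidTransitionStateError(
                f"a minimum must have no imaginary modes, found {n_imag}"
            )

    @property
    def real_modes(self) -> np.ndarray:
        return np.array([w for w in self.wavenumbers if w > 0], dtype=float)


@dataclass(frozen=True)
class ThermoResult:
    """RRHO thermal corrections at one temperature.

    `thermal_enthalpy` is the full correction to enthalpy (ZPE + thermal
    internal energy + RT), kcal/mol; `entropy` is cal/(mol·K);
    `gibbs_correction` satisfies H − T·S/1000 exactly by construction.
    """

    temperature: float
    zpe: float
    thermal_enthalpy: float
    entropy: float
    gibbs_correction: float
    breakdown: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "temperature_K": self.temperature,
            "zpe_kcal_mol": self.zpe,
            "thermal_enthalpy_kcal_mol": self.thermal_enthalpy,
            "entropy_cal_mol_K": self.entropy,
            "gibbs_correction_kcal_mol": self.gibbs_correction,
            "breakdown": self.breakdown,
        }
        return json.dumps(payload, indent=2)


def zero_point_energy(freqs: FrequencySet) -> float:
    """ZPE = ½·h·c·Σν over real modes, kcal/mol; the imaginary mode is excluded."""
    return float(0.5 * CM1_TO_KCAL * freqs.real_modes.sum())


def _principal_moments(geometry: Geometry) -> np.ndarray:
    """Principal moments of inertia, amu·Å², ascending."""
    m = geometry.masses()
    x = geometry.coords - np.average(geometry.coords, axis=0, weights=m)
    tensor = np.zeros((3, 3))
    r2 = np.sum(x**2, axis=1)
    tensor += np.eye(3) * np.sum(m * r2)
    tensor -= np.einsum("k,ki,kj->ij", m, x, x)
    return np.sort(np.linalg.eigvalsh(tensor))


def rrho_corrections(
    geometry: Geometry,
    freqs: FrequencySet,
    temperature: float,
    symmetry_number: int = 1,
) -> ThermoResult:
    """Translational + rotational + vibrational ideal-gas corrections.

    Translational entropy is Sackur–Tetrode at 1 atm; rotation is classical
    (linear and nonlinear tops handled, single atoms get zero rotational
    terms); vibrations are harmonic oscillators over the real modes only.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    T = temperature
    mass_kg = geometry.masses().sum() * AMU

    # --- translation (per mole)
    lam = H_PLANCK / math.sqrt(2 * math.pi * mass_kg * K_B * T)  # thermal wavelength, m
    q_trans = (K_B * T / P_STANDARD) / lam**3
    s_trans = R_CAL * (math.log(q_trans) + 2.5)  # cal/(mol·K)
    e_trans = 1.5 * R_KCAL * T  # kcal/mol

    # --- rotation
    moments = _principal_moments(geometry)  # amu·Å²
    moments_si = moments * AMU * 1e-20  # kg·m²
    nonzero = moments_si[moments * 1.0 > _LINEAR_MOMENT_TOL]
    if len(geometry) == 1 or len(nonzero) == 0:
        s_rot, e_rot = 0.0, 0.0
    elif len(nonzero) == 2 or (
        len(nonzero) == 3 and moments[0] < _LINEAR_MOMENT_TOL
    ):
        # linear rotor: the two large, equal moments
        i_lin = nonzero[-1]
        theta = H_PLANCK**2 / (8 * math.pi**2 * i_lin * K_B)
        q_rot = T / (symmetry_number * theta)
        s_rot = R_CAL * (math.log(q_rot) + 1.0)
        e_rot = R_KCAL * T
    else:
        thetas = H_PLANCK**2 / (8 * math.pi**2 * moments_si * K_B)
        q_rot = math.sqrt(math.pi) / symmetry_number * math.sqrt(T**3 / np.prod(thetas))
        s_rot = R_CAL * (math.log(q_rot) + 1.5)
        e_rot = 1.5 * R_KCAL * T

    # --- vibration (real modes only)
    zpe = zero_point_energy(freqs)
    nus = freqs.real_modes
    if nus.size:
        theta_v = H_PLANCK * C_LIGHT * 100.0 * nus / K_B  # K
        x = theta_v / T
        expm = np.expm1(x)
        e_vib = float(R_KCAL * np.sum(theta_v / expm))
        s_vib = float(R_CAL * np.sum(x / expm - np.log(-np.expm1(-x))))
    else:
        e_vib, s_vib = 0.0, 0.0

    entropy = s_trans + s_rot + s_vib
    thermal_enthalpy = zpe + e_trans + e_rot + e_vib + R_KCAL * T
    gibbs = thermal_enthalpy - T * entropy / 1000.0
    return ThermoResult(
        temperature=T,
        zpe=zpe,
        thermal_enthalpy=thermal_enthalpy,
        entropy=entropy,
        gibbs_correction=gibbs,
        breakdown={
            "s_trans": s_trans,
            "s_rot": s_rot,
            "s_vib": s_vib,
            "e_trans": e_trans,
            "e_rot": e_rot,
            "e_vib_thermal": e_vib,
            "zpe": zpe,
            "pv_rt": R_KCAL * T,
        },
    )


def activation_free_energy(g_reactants: float, g_ts: float) -> float:
    """ΔG‡ = G(TS) − ΣG(reactants), kcal/mol; negative values warn, not fail."""
    if not (math.isfinite(g_reactants) and math.isfinite(g_ts)):
        raise ValueError("free energies must be finite")
    dg = g_ts - g_reactants
    if dg < 0:
        warnings.warn(
            f"negative activation free energy ({dg:.3f} kcal/mol) — barrierless "
            "or inconsistent inputs",
            stacklevel=2,
        )
    return dg
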