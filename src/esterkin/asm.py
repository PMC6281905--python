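"""Activation strain (distortion/interaction) decomposition of a barrier.

The electronic activation energy of the rate-determining attack is split as

    ΔE‡_act = ΔE‡_dist + ΔE‡_int

where ΔE‡_dist is the energy cost of deforming each separated fragment
(ester, water nucleophile) from its equilibrium geometry to the geometry it
adopts in the transition state, and ΔE‡_int is the interaction energy between
the deformed fragments at the TS.  All energies are kcal/mol internally;
hartree inputs are converted at construction with an explicit unit tag —
never inferred.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .constants import HARTREE_TO_KCAL
from .errors import ReferenceMismatchError

__all__ = [
    "FragmentEnergies",
    "ASMResult",
    "distortion_energy",
    "interaction_energy",
    "decompose",
]

_UNIT_FACTORS = {"kcal/mol": 1.0, "kcal": 1.0, "hartree": HARTREE_TO_KCAL, "au": HARTREE_TO_KCAL}


@dataclass(frozen=True)
class FragmentEnergies:
    """Supersystem TS energy plus per-fragment single points, kcal/mol.

    ``fragments`` is a tuple of (label, E at TS geometry, E at own equilibrium).
    """

    e_supersystem_ts: float
    fragments: tuple[tuple[str, float, float], ...]
    reference_note: str = ""

    def __post_init__(self) -> None:
        if len(self.fragments) < 2:
            raise ValueError("need ≥2 fragments (ester + nucleophile)")
        vals = [self.e_supersystem_ts] + [v for _, a, b in self.fragments for v in (a, b)]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all energies must be finite")
        labels = [lab for lab, _, _ in self.fragments]
        if len(set(labels)) != len(labels):
            raise ValueError("fragment labels must be unique")

    @classmethod
    def from_values(cls, e_supersystem_ts, fragments, unit="kcal/mol", reference_note=""):
        """Build with an explicit unit tag ('kcal/mol' or 'hartree')."""
        try:
            f = _UNIT_FACTORS[unit.lower()]
        except KeyError:
            raise ValueError(f"unknown energy unit {unit!r}") from None
        frags = tuple((lab, a * f, b * f) for lab, a, b in fragments)
        return cls(e_supersystem_ts * f, frags, reference_note)

    @property
    def equilibrium_sum(self) -> float:
        return sum(b for _, _, b in self.fragments)

    @property
    def ts_geometry_sum(self) -> float:
        return sum(a for _, a, _ in self.fragments)


@dataclass(frozen=True)
class ASMResult:
    """Distortion / interaction / activation split; additivity holds exactly."""

    distortion: float
    interaction: float
    activation: float
    per_fragment_distortion: dict[str, float]
    reference_deviation: float = 0.0  # nonzero only for complex-referenced input

    def to_json(self) -> str:
        return json.dumps(
            {
                "distortion_kcal_mol": self.distortion,
                "interaction_kcal_mol": self.interaction,
                "activation_kcal_mol": self.activation,
                "per_fragment_distortion": self.per_fragment_distortion,
                "reference_deviation_kcal_mol": self.reference_deviation,
            },
            indent=2,
        )


def distortion_energy(fe: FragmentEnergies) -> float:
    """Σ_i [E_i(TS geometry) − E_i(equilibrium)], kcal/mol."""
    return sum(a - b for _, a, b in fe.fragments)


def per_fragment_distortion(fe: FragmentEnergies) -> dict[str, float]:
    return {lab: a - b for lab, a, b in fe.fragments}


def interaction_energy(fe: FragmentEnergies) -> float:
    """E(supersystem at TS) − Σ_i E_i(TS geometry), kcal/mol."""
    return fe.e_supersystem_ts - fe.ts_geometry_sum


def decompose(
    fe: FragmentEnergies,
    reactant_reference_energy: float | None = None,
    tol: float = 1e-6,
) -> ASMResult:
    """Full two-term activation-strain split.

    With the default separated-fragment reference (Σ equilibrium energies) the
    identity activation = distortion + interaction holds to machine precision.
    An explicit pre-reaction-complex reference is accepted only with a
    ``reference_note`` on the input; the deviation from additivity is then
    reported, not hidden.
    """
    if reactant_reference_energy is None:
        reference = fe.equilibrium_sum
    else:
        reference = reactant_reference_energy
        if abs(reference - fe.equilibrium_sum) > tol and not fe.reference_note:
            raise ReferenceMismatchError(
                f"reference {reference} differs from separated-fragment sum "
                f"{fe.equilibrium_sum} by more than {tol} kcal/mol and no "
                "reference_note explains it"
            )
    dist = distortion_energy(fe)
    inter = interaction_energy(fe)
    act = fe.e_supersystem_ts - reference
    return ASMResult(
        distortion=dist,
        interaction=inter,
        activation=act,
        per_fragment_distortion=per_fragment_distortion(fe),
        reference_deviation=act - (dist + inter),
    )
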