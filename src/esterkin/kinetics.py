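"""Eyring transition-state-theory kinetics.

k(T) = (k_B·T)/(h·c°) · exp(−ΔG‡ / RT)

with the transmission coefficient fixed at 1 and c° = 1 (dimensionless) by
default.  Rates are handled in log space internally so that barriers of
40+ kcal/mol (k ~ 10⁻²⁰ s⁻¹ and below) neither underflow nor lose precision;
forward and inverse evaluation are mutual inverses to better than 1e-10
relative across the entire physically interesting range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .constants import R_KCAL, eyring_prefactor

__all__ = [
    "RateResult",
    "eyring_rate",
    "invert_eyring",
    "half_life",
    "stability_ratio",
    "round_sig",
    "format_sci",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class RateResult:
    """A first-order rate constant with its TST provenance."""

    log_rate: float  # natural log of k/s⁻¹ — the authoritative field
    temperature: float
    activation_free_energy: float  # kcal/mol
    standard_state_factor: float = 1.0

    @property
    def rate_constant(self) -> float:
        """k in s⁻¹ (may underflow to 0 for absurd barriers; use log_rate then)."""
        return math.exp(self.log_rate)

    @property
    def half_life(self) -> float:
        """t½ = ln 2 / k, s."""
        return LN2 * math.exp(-self.log_rate)


def eyring_rate(dg_act: float, temperature: float, c_std: float = 1.0) -> RateResult:
    """Forward Eyring evaluation; `dg_act` in kcal/mol, result in s⁻¹."""
    if not math.isfinite(dg_act):
        raise ValueError("activation free energy must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if c_std <= 0:
        raise ValueError("standard-state factor must be positive")
    log_k = math.log(eyring_prefactor(temperature) / c_std) - dg_act / (R_KCAL * temperature)
    return RateResult(
        log_rate=log_k,
        temperature=temperature,
        activation_free_energy=dg_act,
        standard_state_factor=c_std,
    )


def invert_eyring(k: float, temperature: float, c_std: float = 1.0) -> float:
    """ΔG‡ (kcal/mol) that reproduces rate `k` (s⁻¹) at `temperature`."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature * (math.log(eyring_prefactor(temperature) / c_std) - math.log(k))


def half_life(k: float) -> float:
    """First-order half-life ln2/k, s."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return LN2 / k


def stability_ratio(k_slow: float, k_fast: float) -> float:
    """How many times more stable the slow-hydrolysing species is: k_fast/k_slow."""
    if k_slow <= 0 or k_fast <= 0:
        raise ValueError("rate constants must be positive")
    ratio = k_fast / k_slow
    if ratio < 1.0:
        warnings.warn(
            "stability_ratio < 1: arguments appear swapped (k_slow > k_fast)",
            stacklevel=2,
        )
    return ratio


def round_sig(x: float, sig: int) -> float:
    """Round to `sig` significant figures (as printed rate tables are)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig - 1}e}")


def format_sci(x: float, sig: int = 3) -> str:
    """Scientific-notation rendering matching printed rate-table style."""
    if x == 0:
        return "0"
    s = f"{x:.{sig - 1}e}"
    mant, exp = s.split("e")
    e = int(exp)
    if -5 < e < 4:
        return f"{x:.{max(sig - 1 - e, 0)}f}".rstrip("0").rstrip(".") or "0"
    return f"{mant}e{e:+03d}"
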