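"""Element data: covalent radii and atomic masses.

Covalent radii are the Cordero et al. (2008) single-bond values in Å, embedded
as data because bond perception must be reproducible independent of any
external periodic-table package.  Masses are standard atomic weights in amu.
Only elements plausibly present in (thio/arsa/phospho-)ester chemistry and
nucleic-acid strands are tabulated; asking for anything else raises
`UnknownElementError` rather than guessing.
"""

from __future__ import annotations


class UnknownElementError(KeyError):
    """Element symbol with no tabulated covalent radius / mass."""


# symbol -> (covalent radius Å [Cordero 2008], atomic mass amu)
_ELEMENTS: dict[str, tuple[float, float]] = {
    "H": (0.31, 1.008),
    "C": (0.76, 12.011),   # sp3 value
    "N": (0.71, 14.007),
    "O": (0.66, 15.999),
    "F": (0.57, 18.998),
    "Na": (1.66, 22.990),
    "Mg": (1.41, 24.305),
    "P": (1.07, 30.974),
    "S": (1.05, 32.06),
    "Cl": (1.02, 35.45),
    "K": (2.03, 39.098),
    "Ca": (1.76, 40.078),
    "Fe": (1.32, 55.845),
    "Zn": (1.22, 65.38),
    "As": (1.19, 74.922),
    "Se": (1.20, 78.971),
    "Br": (1.20, 79.904),
    "Ar": (1.06, 39.948),
    "He": (0.28, 4.003),
    "Ne": (0.58, 20.180),
}


def normalize_symbol(symbol: str) -> str:
    """Canonical capitalisation ('AS' -> 'As'); raises on unknown symbols."""
    s = symbol.strip().capitalize()
    if s not in _ELEMENTS:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}")
    return s


def covalent_radius(symbol: str) -> float:
    """Cordero single-bond covalent radius, Å."""
    return _ELEMENTS[normalize_symbol(symbol)][0]


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight, amu."""
    return _ELEMENTS[normalize_symbol(symbol)][1]


def is_known(symbol: str) -> bool:
    try:
        normalize_symbol(symbol)
        return True
    except UnknownElementError:
        return False
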