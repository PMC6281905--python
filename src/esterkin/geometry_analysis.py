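"""Internal-coordinate measurements, reactant-vs-TS tables and Kabsch RMSD.

Distances are Å, angles/dihedrals degrees.  All measurements are invariant
under rigid rotation/translation.  The reactant/TS comparison table mirrors
the way geometry changes along the rate-determining hydrolysis step are
usually tabulated: one labelled internal coordinate per row, its value in the
reactant, in the transition state, and the difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .io_structures import Geometry

__all__ = [
    "distance",
    "angle",
    "dihedral",
    "ParamSpec",
    "GeometryTable",
    "parameter_table",
    "Superposition",
    "kabsch_superpose",
    "pair_by_residue_atom_name",
]


def _check_indices(geometry: Geometry, idx) -> None:
    n = len(geometry)
    for i in idx:
        if not (0 <= i < n):
            raise GeometryError(f"atom index {i} out of range for {n}-atom geometry")
    if len(set(idx)) != len(idx):
        raise GeometryError(f"atom indices must be distinct, got {idx}")


def distance(geometry: Geometry, i: int, j: int) -> float:
    """Euclidean distance between atoms i and j, Å."""
    _check_indices(geometry, (i, j))
    c = geometry.coords
    return float(np.linalg.norm(c[i] - c[j]))


def angle(geometry: Geometry, i: int, j: int, k: int) -> float:
    """Bond angle i–j–k with vertex j, degrees in [0, 180]."""
    _check_indices(geometry, (i, j, k))
    c = geometry.coords
    u, v = c[i] - c[j], c[k] - c[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError(f"zero-length arm in angle ({i},{j},{k})")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(geometry: Geometry, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion i–j–k–l in (−180, 180], degrees (IUPAC sign convention)."""
    _check_indices(geometry, (i, j, k, l))
    c = geometry.coords
    b1, b2, b3 = c[j] - c[i], c[k] - c[j], c[l] - c[k]
    n2 = np.linalg.norm(b2)
    if n2 < 1e-12:
        raise GeometryError("degenerate dihedral axis (coincident middle atoms)")
    m1 = np.cross(b1, b2)
    m2 = np.cross(b2, b3)
    if np.linalg.norm(m1) < 1e-10 or np.linalg.norm(m2) < 1e-10:
        raise GeometryError("collinear atoms make the dihedral undefined")
    x = np.dot(m1, m2)
    y = np.dot(np.cross(m1, m2), b2) / n2
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(ang, -180.0) else ang


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

_KIND_ARITY = {"distance": 2, "angle": 3, "dihedral": 4}
_KIND_UNITS = {"distance": "Å", "angle": "deg", "dihedral": "deg"}


@dataclass(frozen=True)
class ParamSpec:
    """One internal coordinate named by atom roles (e.g. E, O_L, O_p, O3', O5').

    ``role_map`` resolves each role label to an atom index of a particular
    geometry; reactant and TS may map the same role to different indices.
    """

    kind: str
    label: str
    atom_roles: tuple[str, ...]
    role_map: dict[str, dict[str, int]]  # geometry key ("reactant"/"ts") -> role -> index

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ARITY:
            raise ValueError(f"kind must be one of {sorted(_KIND_ARITY)}")
        if len(self.atom_roles) != _KIND_ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} needs {_KIND_ARITY[self.kind]} roles, got {self.atom_roles}"
            )

    def indices(self, which: str) -> tuple[int, ...]:
        try:
            m = self.role_map[which]
            return tuple(m[r] for r in self.atom_roles)
        except KeyError as exc:
            raise GeometryError(f"spec {self.label!r}: missing role mapping {exc}") from exc

    @property
    def units(self) -> str:
        return _KIND_UNITS[self.kind]


_MEASURE = {"distance": distance, "angle": angle, "dihedral": dihedral}


@dataclass
class GeometryTable:
    """Rows of (spec, reactant value, TS value, delta); delta = TS − reactant."""

    rows: list[tuple[ParamSpec, float, float, float]] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "parameter": s.label,
                "kind": s.kind,
                "units": s.units,
                "reactant": r,
                "ts": t,
                "delta": d,
            }
            for s, r, t, d in self.rows
        ]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame.from_records(self.to_records())

    def to_tsv(self) -> str:
        """2-decimal rendering, matching the precision such tables are printed at."""
        lines = ["parameter\tkind\tunits\treactant\tts\tdelta"]
        for rec in self.to_records():
            lines.append(
                f"{rec['parameter']}\t{rec['kind']}\t{rec['units']}\t"
                f"{rec['reactant']:.2f}\t{rec['ts']:.2f}\t{rec['delta']:.2f}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(self.to_records(), indent=2)


def parameter_table(reactant: Geometry, ts: Geometry, specs) -> GeometryTable:
    """Measure every spec on both geometries; delta is exactly ts − reactant."""
    rows = []
    for spec in specs:
        fn = _MEASURE[spec.kind]
        try:
            v_r = fn(reactant, *spec.indices("reactant"))
            v_t = fn(ts, *spec.indices("ts"))
        except GeometryError as exc:
            raise GeometryError(f"parameter {spec.label!r}: {exc}") from exc
        rows.append((spec, v_r, v_t, v_t - v_r))
    return GeometryTable(rows)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform mobile → reference and its residual RMSD (Å)."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,), Å
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "rmsd": self.rmsd,
                "n_pairs": self.n_pairs,
            },
            indent=2,
        )


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray, correspondence=None) -> Superposition:
    """Least-squares optimal rigid superposition (Kabsch, SVD form).

    `correspondence` is an optional sequence of (ref_index, mobile_index)
    pairs; by default row i pairs with row i.  The returned rotation includes
    the determinant correction, so it is always proper (det = +1).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if correspondence is not None:
        pairs = list(correspondence)
        ref = ref[[p[0] for p in pairs]]
        mob = mob[[p[1] for p in pairs]]
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError("reference and mobile must be matching (N, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError(f"superposition needs ≥3 matched pairs, got {n}")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    # collinearity check: rank of centred reference < 2 leaves rotation underdetermined
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise GeometryError("matched atoms are collinear — superposition is degenerate")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def pair_by_residue_atom_name(
    reference: Geometry, mobile: Geometry, include_hydrogens: bool = False
) -> list[tuple[int, int]]:
    """1:1 correspondence on (chain, residue number, atom name).

    Heavy atoms only by default — hydrogens are frequently absent from crystal
    structures, so including them would bias the pairing.
    """

    def key(a):
        return (a.chain_id, a.residue_number, a.name)

    mob_index = {}
    for j, a in enumerate(mobile.atoms):
        if a.element == "H" and not include_hydrogens:
            continue
        mob_index.setdefault(key(a), j)
    pairs = []
    for i, a in enumerate(reference.atoms):
        if a.element == "H" and not include_hydrogens:
            continue
        j = mob_index.get(key(a))
        if j is not None:
            pairs.append((i, j))
    return pairs
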