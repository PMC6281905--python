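"""Molecular structure I/O, bond perception and reaction-centre detection.

Containers
----------
`Atom` / `Geometry` hold labelled Cartesian coordinates (Å) plus optional
strand metadata (atom name, residue, chain).  `BondGraph` is a plain symmetric
adjacency over 0-based atom indices; all bonds are single (no order
perception).

Conventions
-----------
* Internal atom indices are 0-based throughout the package; PDB/XYZ serials
  are 1-based and preserved on write.
* Coordinates are always Å.
* Bond perception: i–j bonded iff d(i,j) ≤ scale·(r_cov(i)+r_cov(j)) with
  Cordero radii and a default scale of 1.15.

PDB reading/writing is delegated to biotite (ATOM/HETATM subset, v3.3
fixed-width columns); the element column takes precedence, with biotite's
atom-name heuristic as fallback for blank columns.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from . import elements
from .errors import (
    ConfigurationError,
    EmptyStructureError,
    NotAnEsterError,
    ParseError,
)

__all__ = [
    "Atom",
    "Geometry",
    "BondGraph",
    "ReactionCenter",
    "read_xyz",
    "write_xyz",
    "read_pdb_subset",
    "write_pdb",
    "perceive_bonds",
    "identify_reaction_center",
]

ROLES = ("reactant", "transition_state", "fragment", "reference")


@dataclass(frozen=True)
class Atom:
    """One labelled atom: element, Cartesian coordinates (Å), 1-based serial."""

    element: str
    coordinates: tuple[float, float, float]
    serial: int
    name: str | None = None
    residue_name: str | None = None
    residue_number: int | None = None
    chain_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "element", elements.normalize_symbol(self.element))
        xyz = tuple(float(c) for c in self.coordinates)
        if len(xyz) != 3 or not all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.serial}: coordinates must be 3 finite numbers")
        object.__setattr__(self, "coordinates", xyz)
        if self.serial < 1:
            raise ValueError("atom serial must be a positive integer")


@dataclass
class Geometry:
    """An ordered collection of atoms with a net charge, label and role."""

    atoms: list[Atom]
    charge: int = 0
    label: str = ""
    role: str = "fragment"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Geometry must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of coordinates, Å."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def symbols(self) -> list[str]:
        return [a.element for a in self.atoms]

    def masses(self) -> np.ndarray:
        """(N,) atomic masses, amu."""
        return np.array([elements.atomic_mass(a.element) for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        """Copy of this geometry with replaced coordinates (same atoms/metadata)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coordinates=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Geometry(atoms, charge=self.charge, label=self.label, role=self.role)


@dataclass
class BondGraph:
    """Symmetric single-bond adjacency over 0-based atom indices."""

    adjacency: dict[int, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, nbrs in self.adjacency.items():
            if i in nbrs:
                raise ValueError(f"self-edge at atom index {i}")
            for j in nbrs:
                if i not in self.adjacency.get(j, set()):
                    raise ValueError(f"asymmetric edge {i}-{j}")

    @classmethod
    def from_edges(cls, n_atoms: int, edges) -> "BondGraph":
        adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
        for i, j in edges:
            if not (0 <= i < n_atoms and 0 <= j < n_atoms):
                raise ValueError(f"edge ({i},{j}) outside atom range")
            adj[i].add(j)
            adj[j].add(i)
        return cls(adj)

    def neighbors(self, i: int) -> set[int]:
        return set(self.adjacency.get(i, set()))

    def degree(self, i: int) -> int:
        return len(self.adjacency.get(i, set()))

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (i, j) for i, nbrs in self.adjacency.items() for j in nbrs if i < j
        )

    def bfs_distances(self, source: int) -> dict[int, int]:
        """Graph (bond-count) distance from `source` to every reachable atom."""
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for u in frontier:
                for v in self.adjacency.get(u, set()):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    def is_connected(self) -> bool:
        if not self.adjacency:
            return True
        start = next(iter(self.adjacency))
        return len(self.bfs_distances(start)) == len(self.adjacency)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.adjacency)
        g.add_edges_from(self.edges())
        return g


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(text: str, charge: int = 0, label: str = "", role: str = "fragment") -> Geometry:
    """Parse standard XYZ text (count line, comment, `El x y z` records)."""
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"line 1: malformed atom count {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) < n:
        raise ParseError(f"header claims {n} atoms but only {len(records)} records found")
    atoms = []
    for k, ln in enumerate(records[:n]):
        lineno = k + 3
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"line {lineno}: expected 'element x y z', got {ln!r}")
        sym = parts[0]
        if not elements.is_known(sym):
            raise ParseError(f"line {lineno}: unknown element {sym!r}")
        try:
            x, y, z = (float(v) for v in parts[1:4])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric coordinate in {ln!r}") from None
        atoms.append(Atom(sym, (x, y, z), serial=k + 1))
    return Geometry(atoms, charge=charge, label=label or comment.strip(), role=role)


def write_xyz(geometry: Geometry, comment: str | None = None) -> str:
    """Serialize to XYZ with 8-decimal coordinates (lossless to ≪1e-6 Å)."""
    lines = [str(len(geometry)), comment if comment is not None else geometry.label]
    for a in geometry.atoms:
        x, y, z = a.coordinates
        lines.append(f"{a.element:<2s} {x:16.8f} {y:16.8f} {z:16.8f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB (ATOM/HETATM subset via biotite)
# ---------------------------------------------------------------------------

def read_pdb_subset(text: str, charge: int = 0, label: str = "", role: str = "fragment") -> Geometry:
    """Parse the ATOM/HETATM records of PDB text into a Geometry.

    Residue/chain metadata is preserved; every non-coordinate record type is
    ignored.  The element column wins; blank columns fall back to the
    atom-name convention.
    """
    from biotite.structure.io.pdb import PDBFile

    if not any(ln.startswith(("ATOM", "HETATM")) for ln in text.splitlines()):
        raise EmptyStructureError("no ATOM/HETATM records in PDB input")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # element-guessed-from-name notices
            pdb = PDBFile.read(io.StringIO(text))
            arr = pdb.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises assorted types on bad columns
        raise ParseError(f"PDB parse failed: {exc}") from exc
    atoms = []
    for k in range(arr.array_length()):
        sym = str(arr.element[k]).strip()
        if not elements.is_known(sym):
            raise ParseError(f"atom serial {int(arr.atom_id[k])}: unknown element {sym!r}")
        atoms.append(
            Atom(
                element=sym,
                coordinates=tuple(float(c) for c in arr.coord[k]),
                serial=int(arr.atom_id[k]) if arr.atom_id[k] > 0 else k + 1,
                name=str(arr.atom_name[k]),
                residue_name=str(arr.res_name[k]),
                residue_number=int(arr.res_id[k]),
                chain_id=str(arr.chain_id[k]),
            )
        )
    return Geometry(atoms, charge=charge, label=label, role=role)


def write_pdb(geometry: Geometry, b_factors=None) -> str:
    """Serialize ATOM records via biotite; `b_factors` lets callers tag layers."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(geometry)
    arr = struc.AtomArray(n)
    arr.coord = geometry.coords
    for k, a in enumerate(geometry.atoms):
        arr.element[k] = a.element.upper()
        arr.atom_name[k] = a.name or a.element
        arr.res_name[k] = a.residue_name or "UNK"
        arr.res_id[k] = a.residue_number if a.residue_number is not None else 1
        arr.chain_id[k] = a.chain_id or "A"
    arr.set_annotation("atom_id", np.array([a.serial for a in geometry.atoms]))
    bf = np.zeros(n) if b_factors is None else np.asarray(b_factors, dtype=float)
    if bf.shape != (n,):
        raise ValueError("b_factors must have one value per atom")
    arr.set_annotation("b_factor", bf)
    arr.set_annotation("occupancy", np.ones(n))
    pdb = PDBFile()
    pdb.set_structure(arr)
    return "\n".join(pdb.lines) + "\n"


# ---------------------------------------------------------------------------
# Bond perception & reaction centre
# ---------------------------------------------------------------------------

def perceive_bonds(geometry: Geometry, scale: float = 1.15) -> BondGraph:
    """Distance-based single-bond perception with Cordero covalent radii."""
    if scale <= 0:
        raise ConfigurationError(f"scale must be positive, got {scale}")
    try:
        radii = np.array([elements.covalent_radius(a.element) for a in geometry.atoms])
    except elements.UnknownElementError as exc:
        raise ConfigurationError(str(exc)) from exc
    coords = geometry.coords
    d = cdist(coords, coords)
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonded = (d <= cutoff) & ~np.eye(len(geometry), dtype=bool)
    ii, jj = np.nonzero(np.triu(bonded))
    return BondGraph.from_edges(len(geometry), zip(ii.tolist(), jj.tolist()))


@dataclass(frozen=True)
class ReactionCenter:
    """The As/P atom a water nucleophile attacks, plus tie-break metadata."""

    index: int
    element: str
    n_bonded_oxygen: int
    ambiguous: bool = False


def identify_reaction_center(geometry: Geometry, bondgraph: BondGraph) -> ReactionCenter:
    """Pick the As or P atom bonded to the most oxygens.

    Ties are broken by lowest atom serial and flagged ``ambiguous``.
    """
    symbols = geometry.symbols
    candidates = [i for i, s in enumerate(symbols) if s in ("As", "P")]
    if not candidates:
        raise NotAnEsterError("no As or P atom present — not an arsenate/phosphate ester")

    def n_oxy(i: int) -> int:
        return sum(1 for j in bondgraph.neighbors(i) if symbols[j] == "O")

    scores = {i: n_oxy(i) for i in candidates}
    best = max(scores.values())
    winners = [i for i in candidates if scores[i] == best]
    winners.sort(key=lambda i: geometry.atoms[i].serial)
    chosen = winners[0]
    return ReactionCenter(
        index=chosen,
        element=symbols[chosen],
        n_bonded_oxygen=best,
        ambiguous=len(winners) > 1,
    )
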