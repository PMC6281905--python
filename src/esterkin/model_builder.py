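"""Ester classification, As-for-P substitution and two-layer QM/MM partitioning.

Classification follows the three structural classes of biological
phosphate/arsenate esters:

* class 1A — monoester whose leaving group runs O–P–R (anhydride-like, e.g.
  pyrophosphate / pyroarsenate);
* class 1B — monoester with an O–C–R leaving group (sugar esters such as
  ribose-1-phosphate);
* class 2  — diester with two O–C bridges (nucleic-acid backbone linkages).

The QM/MM partition rule cuts only non-polar bonds between two sp³ carbons
lying more than `min_graph_distance` bonds from the reaction centre, chooses
the smallest connected QM region containing the centre, and saturates each
cut with a hydrogen link atom at 1.09 Å along the severed bond axis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .elements import covalent_radius
from .errors import EsterkinError, SubstitutionError, UnsupportedEsterError
from .io_structures import (
    Atom,
    BondGraph,
    Geometry,
    identify_reaction_center,
    perceive_bonds,
)

__all__ = [
    "EsterClassification",
    "OniomPartition",
    "classify_ester",
    "substitute_central_atoms",
    "partition_oniom",
    "extract_strand",
]

LINK_CH_DISTANCE = 1.09  # Å, standard C–H used for link-atom placement


@dataclass(frozen=True)
class EsterClassification:
    """Structural class of an As/P ester and its anionic state."""

    ester_class: str  # "1A" | "1B" | "2"
    ester_type: str  # "monoester" | "diester"
    leaving_group_pattern: str  # "O-P-R" | "O-C-R"
    central_atom: str  # "As" | "P"
    anionic_state: str  # "mono" | "di"
    center_index: int
    center_ambiguous: bool = False

    def __post_init__(self) -> None:
        valid = {
            "1A": ("monoester", "O-P-R"),
            "1B": ("monoester", "O-C-R"),
            "2": ("diester", "O-C-R"),
        }
        if self.ester_class not in valid:
            raise ValueError(f"unknown ester class {self.ester_class!r}")
        etype, pattern = valid[self.ester_class]
        if (self.ester_type, self.leaving_group_pattern) != (etype, pattern):
            raise ValueError(
                f"class {self.ester_class} requires ({etype}, {pattern}), got "
                f"({self.ester_type}, {self.leaving_group_pattern})"
            )
        if self.central_atom not in ("As", "P"):
            raise ValueError("central atom must be As or P")
        if self.anionic_state not in ("mono", "di"):
            raise ValueError("anionic state must be 'mono' or 'di'")


def classify_ester(geometry: Geometry, bondgraph: BondGraph) -> EsterClassification:
    """Classify by walking the bridging oxygens away from the reaction centre.

    A bridging (ester) oxygen is an O bonded to the centre and to at least one
    further non-hydrogen heavy atom.  One bridge ⇒ monoester, two ⇒ diester;
    phosphorus beyond the bridge ⇒ the O–P–R pattern of class 1A, carbon ⇒
    O–C–R (1B for monoesters, 2 for diesters).
    """
    center = identify_reaction_center(geometry, bondgraph)
    symbols = geometry.symbols
    bridges: list[tuple[int, list[str]]] = []
    for o in sorted(bondgraph.neighbors(center.index)):
        if symbols[o] != "O":
            continue
        beyond = [
            symbols[k]
            for k in bondgraph.neighbors(o)
            if k != center.index and symbols[k] != "H"
        ]
        if beyond:
            bridges.append((o, beyond))
    if len(bridges) == 0 or len(bridges) > 2:
        raise UnsupportedEsterError(
            f"{len(bridges)} bridging linkages found; only mono- and diesters "
            "are classified"
        )
    beyond_elements = {el for _, els in bridges for el in els}
    if "P" in beyond_elements or "As" in beyond_elements:
        pattern = "O-P-R"
    elif "C" in beyond_elements:
        pattern = "O-C-R"
    else:
        raise UnsupportedEsterError(
            f"bridging oxygen leads to unsupported elements {sorted(beyond_elements)}"
        )
    ester_type = "monoester" if len(bridges) == 1 else "diester"
    if pattern == "O-P-R":
        if ester_type != "monoester":
            raise UnsupportedEsterError("diesters with O-P-R linkages are not classified")
        ester_class = "1A"
    else:
        ester_class = "1B" if ester_type == "monoester" else "2"
    if geometry.charge == -1:
        anionic = "mono"
    elif geometry.charge == -2:
        anionic = "di"
    else:
        raise UnsupportedEsterError(
            f"net charge {geometry.charge} is neither mono- (−1) nor dianionic (−2)"
        )
    return EsterClassification(
        ester_class=ester_class,
        ester_type=ester_type,
        leaving_group_pattern=pattern,
        central_atom=center.element,
        anionic_state=anionic,
        center_index=center.index,
        center_ambiguous=center.ambiguous,
    )


def substitute_central_atoms(
    geometry: Geometry,
    positions,
    adjust_bonds: bool = False,
    bondgraph: BondGraph | None = None,
) -> Geometry:
    """Replace phosphorus by arsenic at the given 0-based positions.

    With ``adjust_bonds`` every As–O bond of a substituted centre is
    lengthened along its own axis by the covalent-radius difference
    (r_cov(As) − r_cov(P) ≈ +0.12 Å), moving only those oxygens; otherwise
    coordinates are untouched.
    """
    positions = sorted(set(int(p) for p in positions))
    symbols = geometry.symbols
    for p in positions:
        if not (0 <= p < len(geometry)):
            raise SubstitutionError(f"position {p} out of range")
        if symbols[p] != "P":
            raise SubstitutionError(f"atom {p} is {symbols[p]}, not P — cannot substitute")
    atoms = list(geometry.atoms)
    coords = geometry.coords
    if adjust_bonds and positions:
        bg = bondgraph if bondgraph is not None else perceive_bonds(geometry)
        dr = covalent_radius("As") - covalent_radius("P")
        for p in positions:
            for o in bg.neighbors(p):
                if symbols[o] != "O":
                    continue
                axis = coords[o] - coords[p]
                norm = np.linalg.norm(axis)
                if norm < 1e-9:
                    raise SubstitutionError(f"coincident atoms {p} and {o}")
                coords[o] = coords[p] + axis * (norm + dr) / norm
    for p in positions:
        name = atoms[p].name
        atoms[p] = replace(
            atoms[p],
            element="As",
            coordinates=tuple(coords[p]),
            name="As" if name in (None, "P") else name,
        )
    for k, a in enumerate(atoms):
        if k not in positions and not np.allclose(a.coordinates, coords[k]):
            atoms[k] = replace(a, coordinates=tuple(coords[k]))
    return Geometry(atoms, charge=geometry.charge, label=geometry.label, role=geometry.role)


@dataclass(frozen=True)
class OniomPartition:
    """Two-layer QM/MM split: atom sets, cut bonds and hydrogen link atoms."""

    qm_atoms: frozenset[int]
    mm_atoms: frozenset[int]
    cut_bonds: frozenset[tuple[int, int]]  # (QM-side index, MM-side index)
    link_atoms: tuple[tuple[int, int, str, tuple[float, float, float]], ...]
    frozen_mm: bool = True

    def validate(self, geometry: Geometry, bondgraph: BondGraph, center: int,
                 min_graph_distance: int = 4) -> None:
        """Assert every structural invariant of the partition; raises on failure."""
        n = len(geometry)
        assert self.qm_atoms | self.mm_atoms == set(range(n)), "layers not exhaustive"
        assert not (self.qm_atoms & self.mm_atoms), "layers overlap"
        assert center in self.qm_atoms, "reaction centre outside QM layer"
        sub = {i: bondgraph.neighbors(i) & self.qm_atoms for i in self.qm_atoms}
        reach = BondGraph(sub).bfs_distances(center)
        assert set(reach) == self.qm_atoms, "QM region not connected"
        dist = bondgraph.bfs_distances(center)
        symbols = geometry.symbols
        for q, m in self.cut_bonds:
            assert q in self.qm_atoms and m in self.mm_atoms, "cut bond not across layers"
            assert symbols[q] == symbols[m] == "C", "cut bond is not C–C"
            assert bondgraph.degree(q) == 4 and bondgraph.degree(m) == 4, "cut carbon not sp³"
            assert dist.get(q, 10**9) > min_graph_distance, "QM-side cut atom too close to centre"
            assert dist.get(m, 10**9) > min_graph_distance, "MM-side cut atom too close to centre"
        assert len(self.link_atoms) == len(self.cut_bonds), "one link atom per cut bond"

    def to_manifest(self) -> str:
        return json.dumps(
            {
                "qm_atoms": sorted(self.qm_atoms),
                "mm_atoms": sorted(self.mm_atoms),
                "cut_bonds": sorted(map(list, self.cut_bonds)),
                "link_atoms": [
                    {"host_qm": h, "replaced_mm": m, "element": e, "position": list(p)}
                    for h, m, e, p in self.link_atoms
                ],
                "frozen_mm": self.frozen_mm,
            },
            indent=2,
        )

    def layer_b_factors(self, n_atoms: int) -> np.ndarray:
        """Per-atom layer tag for PDB export: 1.00 = QM layer, 0.00 = MM layer."""
        bf = np.zeros(n_atoms)
        bf[sorted(self.qm_atoms)] = 1.0
        return bf


def _eligible_cut_bonds(geometry, bondgraph, center, min_graph_distance):
    symbols = geometry.symbols
    dist = bondgraph.bfs_distances(center)
    out = []
    for i, j in bondgraph.edges():
        if symbols[i] != "C" or symbols[j] != "C":
            continue
        if bondgraph.degree(i) != 4 or bondgraph.degree(j) != 4:
            continue  # topological sp³ test
        if dist.get(i, 10**9) <= min_graph_distance or dist.get(j, 10**9) <= min_graph_distance:
            continue
        out.append((i, j))
    return out


def partition_oniom(
    geometry: Geometry,
    bondgraph: BondGraph,
    center: int,
    min_graph_distance: int = 4,
) -> OniomPartition:
    """Smallest valid QM region around the reaction centre.

    Since a layer boundary may only pass through eligible sp³ C–C bonds, the
    minimal QM region is exactly the connected component of the centre in the
    bond graph with all eligible bonds removed: any smaller region would have
    to sever an ineligible bond.  If no bond is eligible the whole system is
    QM (with a warning) rather than an error.
    """
    if not (0 <= center < len(geometry)):
        raise EsterkinError(f"center index {center} out of range")
    candidates = _eligible_cut_bonds(geometry, bondgraph, center, min_graph_distance)
    if not candidates:
        warnings.warn(
            "no eligible sp³ C–C cut bond beyond the distance threshold — "
            "treating the whole system as the QM layer",
            stacklevel=2,
        )
        return OniomPartition(
            qm_atoms=frozenset(range(len(geometry))),
            mm_atoms=frozenset(),
            cut_bonds=frozenset(),
            link_atoms=(),
        )
    cand = set(candidates) | {(j, i) for i, j in candidates}
    # BFS from the centre refusing to traverse candidate bonds
    qm = {center}
    frontier = [center]
    while frontier:
        nxt = []
        for u in frontier:
            for v in bondgraph.neighbors(u):
                if v in qm or (u, v) in cand:
                    continue
                qm.add(v)
                nxt.append(v)
        frontier = nxt
    mm = set(range(len(geometry))) - qm
    cuts = frozenset(
        (i, j) if i in qm else (j, i)
        for i, j in candidates
        if (i in qm) != (j in qm)
    )
    coords = geometry.coords
    links = []
    for q, m in sorted(cuts):
        axis = coords[m] - coords[q]
        axis /= np.linalg.norm(axis)
        pos = coords[q] + LINK_CH_DISTANCE * axis
        links.append((q, m, "H", tuple(float(x) for x in pos)))
    return OniomPartition(
        qm_atoms=frozenset(qm),
        mm_atoms=frozenset(mm),
        cut_bonds=cuts,
        link_atoms=tuple(links),
    )


def extract_strand(
    geometry: Geometry,
    chain: str,
    residue_range: tuple[int, int],
    cap_termini: bool = False,
) -> Geometry:
    """Atoms of the selected chain/residue window, metadata preserved.

    The window must be contiguous within the chain — a residue number missing
    from the chain inside the window is treated as a chain break and raises.
    With ``cap_termini`` severed backbone oxygens (O3'/O5' that lost their
    bridging P/As) gain a hydroxyl hydrogen; the default leaves the selection
    unmodified.
    """
    lo, hi = residue_range
    if lo > hi:
        raise EsterkinError(f"empty residue range {residue_range}")
    chain_residues = {
        a.residue_number for a in geometry.atoms if a.chain_id == chain
    }
    if not chain_residues:
        raise EsterkinError(f"chain {chain!r} not present")
    missing = [r for r in range(lo, hi + 1) if r not in chain_residues]
    if missing:
        raise EsterkinError(
            f"selection {lo}–{hi} crosses a chain break: residues {missing} absent"
        )
    sel = [
        (i, a)
        for i, a in enumerate(geometry.atoms)
        if a.chain_id == chain and lo <= (a.residue_number or 0) <= hi
    ]
    if not sel:
        raise EsterkinError("empty selection")
    atoms = [a for _, a in sel]
    out = Geometry(atoms, charge=geometry.charge, label=geometry.label, role=geometry.role)
    if cap_termini:
        bg_full = perceive_bonds(geometry)
        keep = {i for i, _ in sel}
        symbols = geometry.symbols
        coords = geometry.coords
        extra = []
        next_serial = max(a.serial for a in atoms) + 1
        for i, a in sel:
            if a.element != "O" or a.name not in ("O3'", "O5'"):
                continue
            severed = [j for j in bg_full.neighbors(i) if j not in keep and symbols[j] in ("P", "As")]
            if not severed:
                continue
            axis = coords[severed[0]] - coords[i]
            axis /= np.linalg.norm(axis)
            pos = coords[i] + 0.96 * axis
            extra.append(
                Atom(
                    "H",
                    tuple(float(x) for x in pos),
                    serial=next_serial,
                    name="HO" + (a.name[1] if a.name else ""),
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    chain_id=a.chain_id,
                )
            )
            next_serial += 1
        if extra:
            out = Geometry(
                atoms + extra, charge=geometry.charge, label=geometry.label, role=geometry.role
            )
    return out
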