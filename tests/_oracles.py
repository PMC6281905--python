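"""Independent reference implementations used only to cross-check the package.

Each function here is deliberately written from scratch against the textbook
definition (or as a brute-force enumeration) and must stay independent of the
code paths it validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.constants as sc


def dihedral_atan2(p0, p1, p2, p3) -> float:
    """Praxeolitic single-atan2 torsion formula, degrees."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def rrho_terms_diatomic(m1_amu, m2_amu, bond_A, nu_cm, T):
    """Closed-form RRHO terms for a heteronuclear diatomic, σ = 1.

    Returns dict of entropies in cal/(mol·K) and energies in kcal/mol,
    evaluated straight from partition-function formulas.
    """
    kB, h, NA = sc.k, sc.h, sc.N_A
    m = (m1_amu + m2_amu) * sc.atomic_mass
    q_t = (2 * math.pi * m * kB * T / h**2) ** 1.5 * kB * T / sc.atm
    s_trans = sc.R / sc.calorie * (math.log(q_t) + 2.5)
    e_trans = 1.5 * sc.R * T / (sc.calorie * 1000)

    mu = (m1_amu * m2_amu) / (m1_amu + m2_amu) * sc.atomic_mass
    inertia = mu * (bond_A * 1e-10) ** 2
    theta_r = h**2 / (8 * math.pi**2 * inertia * kB)
    s_rot = sc.R / sc.calorie * (math.log(T / theta_r) + 1.0)
    e_rot = sc.R * T / (sc.calorie * 1000)

    theta_v = h * sc.c * 100.0 * nu_cm / kB
    x = theta_v / T
    zpe = 0.5 * sc.R * theta_v / (sc.calorie * 1000)
    e_vib = sc.R * theta_v / math.expm1(x) / (sc.calorie * 1000)
    s_vib = sc.R / sc.calorie * (x / math.expm1(x) - math.log(-math.expm1(-x)))
    return {
        "s_trans": s_trans,
        "s_rot": s_rot,
        "s_vib": s_vib,
        "e_trans": e_trans,
        "e_rot": e_rot,
        "e_vib": e_vib,
        "zpe": zpe,
    }


def classify_pattern_oracle(geometry, bondgraph):
    """Subgraph-pattern ester classifier, independent of the package's walker.

    Builds a networkx graph, finds every X(=As/P) with ≥3 O neighbours, then
    matches the O-bridge patterns X–O–P / X–O–C explicitly.
    """
    import networkx as nx

    g = nx.Graph()
    sym = geometry.symbols
    g.add_nodes_from(range(len(geometry)))
    g.add_edges_from(bondgraph.edges())
    centers = [
        i for i in g if sym[i] in ("As", "P")
        and sum(1 for j in g[i] if sym[j] == "O") >= 3
    ]
    if not centers:
        return None
    # mirror the package's serial tie-break to compare like with like
    centers.sort(key=lambda i: (-sum(1 for j in g[i] if sym[j] == "O"),
                                geometry.atoms[i].serial))
    c = centers[0]
    bridge_targets = []
    for o in g[c]:
        if sym[o] != "O":
            continue
        heavy = [k for k in g[o] if k != c and sym[k] != "H"]
        if heavy:
            bridge_targets.append(sorted(sym[k] for k in heavy))
    n = len(bridge_targets)
    if n == 0 or n > 2:
        return None
    flat = {el for group in bridge_targets for el in group}
    if flat & {"P", "As"}:
        cls = "1A" if n == 1 else None
    elif "C" in flat:
        cls = "1B" if n == 1 else "2"
    else:
        cls = None
    return {
        "ester_class": cls,
        "ester_type": "monoester" if n == 1 else "diester",
        "central_atom": sym[c],
        "center_index": c,
    }


def brute_force_min_qm(geometry, bondgraph, center, min_graph_distance=4):
    """Minimal valid QM-region size by exhaustive enumeration of cut sets.

    Only practical for small graphs (≲20 candidate-edge subsets); validity:
    every edge leaving the centre's component must be an eligible sp³ C–C
    bond with both endpoints more than `min_graph_distance` bonds from the
    centre.
    """
    sym = geometry.symbols
    dist = bondgraph.bfs_distances(center)
    candidates = [
        (i, j)
        for i, j in bondgraph.edges()
        if sym[i] == sym[j] == "C"
        and bondgraph.degree(i) == 4
        and bondgraph.degree(j) == 4
        and dist.get(i, 10**9) > min_graph_distance
        and dist.get(j, 10**9) > min_graph_distance
    ]
    all_edges = bondgraph.edges()
    best = None
    for r in range(len(candidates) + 1):
        for cut in itertools.combinations(candidates, r):
            cut_set = set(cut)
            # component of center without cut edges
            adj = {i: set() for i in range(len(geometry))}
            for i, j in all_edges:
                if (i, j) in cut_set or (j, i) in cut_set:
                    continue
                adj[i].add(j)
                adj[j].add(i)
            comp = {center}
            stack = [center]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            boundary = [
                (i, j) for i, j in all_edges if (i in comp) != (j in comp)
            ]
            if all((e in cut_set) or (tuple(reversed(e)) in cut_set) for e in boundary):
                if best is None or len(comp) < best:
                    best = len(comp)
    return best


def random_rigid_transform(rng):
    """Uniform random proper rotation (QR-based) + translation."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-10, 10, 3)
    return q, t
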