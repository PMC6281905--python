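"""Seeded fixture generators with machine-readable ground truth.

Every stage of the pipeline is testable offline because this module emulates
the outputs an electronic-structure workflow would provide:

* idealised tetrahedral ester reactants and trigonal-bipyramidal TS-like
  structures with As or P centres, placed at the published bond lengths and
  angles (`esterkin.data.ESTER_GEOMETRY_TARGETS`);
* fragment-energy sets with prescribed distortion/interaction components;
* reactant/TS species whose RRHO Gibbs difference equals a prescribed ΔG‡,
  solved with a closed-form thermochemistry evaluation written independently
  of `esterkin.thermochem`;
* simplified single-stranded sugar–phosphate models with correct backbone
  connectivity for substitution and QM/MM partition testing.

All generators are pure functions of (parameters, seed).  Coordinates that a
ground-truth quantity depends on are placed exactly; every other coordinate
receives a uniform ±0.01 Å jitter so that bond perception and classification
are exercised on non-idealised input.  Prescribed energy targets are
quantised to a 2⁻²⁰ kcal/mol grid, which makes their recovery by the analysis
code bit-exact rather than merely close.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.constants as _sc

from .asm import FragmentEnergies
from .data import ESTER_GEOMETRY_TARGETS, NUCLEOPHILE_EO_TS, TERMINAL_EO
from .geometry_analysis import ParamSpec
from .io_structures import Atom, BondGraph, Geometry, write_pdb, write_xyz
from .thermochem import FrequencySet

__all__ = [
    "FixtureBundle",
    "make_ideal_ester",
    "make_ts_like",
    "make_fragment_energies",
    "make_thermo_species",
    "make_mock_strand",
    "DEFAULT_ASM_TARGETS",
]

JITTER = 0.01  # Å, uniform, applied to non-asserted coordinates
_GRID = 2.0**20  # energy quantisation grid (≈1e-6 kcal/mol resolution)

#: illustrative (distortion, interaction) kcal/mol per (class, central, anionic),
#: emulating the published qualitative pattern: P esters deform more than As
#: esters in the TS, dianionic more than monoanionic, with interaction pulling
#: the dianionic-monoester barriers down.
DEFAULT_ASM_TARGETS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("1A", "P", "mono"): (52.0, -13.8),
    ("1A", "As", "mono"): (38.0, -15.7),
    ("1A", "P", "di"): (65.0, -27.8),
    ("1A", "As", "di"): (42.0, -23.1),
    ("1B", "P", "mono"): (53.0, -14.0),
    ("1B", "As", "mono"): (37.0, -15.3),
    ("1B", "P", "di"): (66.0, -30.7),
    ("1B", "As", "di"): (43.0, -24.0),
    ("2", "P", "mono"): (58.0, -14.3),
    ("2", "As", "mono"): (40.0, -14.5),
}


@dataclass
class FixtureBundle:
    """One generated fixture plus its recomputable ground truth."""

    kind: str
    seed: int
    geometry: Geometry | None = None
    ts_geometry: Geometry | None = None
    frequencies: dict[str, FrequencySet] = field(default_factory=dict)
    electronic_energies: dict[str, float] = field(default_factory=dict)
    fragment_energies: FragmentEnergies | None = None
    bond_edges: list[tuple[int, int]] | None = None
    indices: dict[str, dict[str, int]] = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)
    extra_geometries: dict[str, Geometry] = field(default_factory=dict)

    def declared_bondgraph(self) -> BondGraph:
        if self.bond_edges is None or self.geometry is None:
            raise ValueError("bundle carries no declared bond topology")
        return BondGraph.from_edges(len(self.geometry), self.bond_edges)

    def param_specs(self) -> list[ParamSpec]:
        """ParamSpecs for the primary reactant/TS internal coordinates."""
        if not self.indices.get("reactant") or not self.indices.get("ts"):
            raise ValueError("bundle has no paired reactant/TS index maps")
        r, t = self.indices["reactant"], self.indices["ts"]
        specs = []
        for q in self.ground_truth.get("parameters", []):
            kind, roles = q["kind"], tuple(q["roles"])
            specs.append(
                ParamSpec(
                    kind=kind,
                    label=q["label"],
                    atom_roles=roles,
                    role_map={
                        "reactant": {role: r[role] for role in roles},
                        "ts": {role: t[role] for role in roles},
                    },
                )
            )
        return specs

    def write(self, directory: str, prefix: str | None = None) -> list[str]:
        """Serialise structures (XYZ; PDB for strands) + a JSON ground-truth sidecar."""
        os.makedirs(directory, exist_ok=True)
        prefix = prefix or self.kind
        written = []

        def _dump(name: str, geom: Geometry) -> None:
            if self.kind == "strand":
                path = os.path.join(directory, f"{prefix}_{name}.pdb")
                text = write_pdb(geom)
            else:
                path = os.path.join(directory, f"{prefix}_{name}.xyz")
                text = write_xyz(geom)
            with open(path, "w") as fh:
                fh.write(text)
            written.append(path)

        if self.geometry is not None:
            _dump("reactant" if self.ts_geometry is not None else "structure", self.geometry)
        if self.ts_geometry is not None:
            _dump("ts", self.ts_geometry)
        sidecar = {
            "kind": self.kind,
            "seed": self.seed,
            "ground_truth": self.ground_truth,
            "indices": self.indices,
            "bond_edges": self.bond_edges,
        }
        path = os.path.join(directory, f"{prefix}_ground_truth.json")
        with open(path, "w") as fh:
            json.dump(sidecar, fh, indent=2)
        written.append(path)
        return written


# ---------------------------------------------------------------------------
# direction helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def _cone(axis: np.ndarray, angle_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at `angle` from `axis`, rotated by `azimuth` about it."""
    axis = _unit(axis)
    p1 = _perp(axis)
    p2 = np.cross(axis, p1)
    a = math.radians(angle_deg)
    az = math.radians(azimuth_deg)
    return math.cos(a) * axis + math.sin(a) * (math.cos(az) * p1 + math.sin(az) * p2)


def _quantize(x: float) -> float:
    return round(x * _GRID) / _GRID


# ---------------------------------------------------------------------------
# ideal esters (reactants)
# ---------------------------------------------------------------------------

def _scaffold_atoms(central: str, ester_class: str, bridge_pos: np.ndarray,
                    e_pos: np.ndarray, azimuth: float, serial0: int, tag: str):
    """Leaving-group atoms beyond one bridging oxygen (O–P–R or O–C–R)."""
    axis = _unit(bridge_pos - e_pos)  # continuation away from the centre
    w = _cone(axis, 60.0, azimuth)  # E–O–X angle of 120°
    atoms = []
    if ester_class == "1A":
        p_pos = bridge_pos + 1.62 * w
        atoms.append(("P", p_pos, f"P{tag}"))
        back = _unit(bridge_pos - p_pos)
        for k in range(3):
            d = _cone(-back, 70.5, 120.0 * k)  # tetrahedral from the O–P bond
            atoms.append(("O", p_pos + 1.50 * d, f"O{tag}{k + 1}"))
    else:
        c_pos = bridge_pos + 1.43 * w
        atoms.append(("C", c_pos, f"C{tag}"))
        back = _unit(bridge_pos - c_pos)
        for k in range(3):
            d = _cone(-back, 70.5, 120.0 * k)
            atoms.append(("H", c_pos + 1.09 * d, f"H{tag}{k + 1}"))
    out = []
    for i, (el, pos, name) in enumerate(atoms):
        out.append(Atom(el, tuple(pos), serial=serial0 + i, name=name))
    return out


def _assemble(records, charge, label, role, rng, exact_names):
    """Build a Geometry, jittering every atom not in `exact_names`."""
    atoms = []
    for a in records:
        if a.name in exact_names:
            atoms.append(a)
        else:
            pos = np.array(a.coordinates) + rng.uniform(-JITTER, JITTER, 3)
            atoms.append(Atom(a.element, tuple(pos), a.serial, a.name,
                              a.residue_name, a.residue_number, a.chain_id))
    return Geometry(atoms, charge=charge, label=label, role=role)


def _reactant_records(central: str, ester_class: str, anionic: str):
    """Exactly-placed atom records plus the names of exactly-placed atoms."""
    t = ESTER_GEOMETRY_TARGETS[(central, ester_class, anionic)]
    r = t["reactant"]
    d_term = TERMINAL_EO[central]
    e = np.zeros(3)
    records = [Atom(central, (0.0, 0.0, 0.0), 1, name=central)]
    serial = 2
    if ester_class in ("1A", "1B"):
        bridge_name = t["bridge_name"]
        u1 = np.array([0.0, 0.0, 1.0])
        theta = r["angle"]
        u2 = _cone(u1, theta, 0.0)
        bridge = r["d_bridge"] * u1
        records.append(Atom("O", tuple(bridge), serial, name=bridge_name)); serial += 1
        records.append(Atom("O", tuple(r["d_op"] * u2), serial, name="Op")); serial += 1
        term_dirs = [_cone(u1, theta, 120.0), _cone(u1, theta, 240.0)]
        term_pos = []
        for k, d in enumerate(term_dirs):
            term_pos.append(d_term * d)
            records.append(Atom("O", tuple(d_term * d), serial, name=f"Ot{k + 1}")); serial += 1
        if anionic == "mono":
            hp = term_pos[0] + 0.96 * term_dirs[0]
            records.append(Atom("H", tuple(hp), serial, name="Hop")); serial += 1
        records.extend(
            _scaffold_atoms(central, ester_class, bridge, e, 180.0, serial, "L")
        )
        exact = {central, bridge_name, "Op"}
        idx = {central: 0, bridge_name: 1, "Op": 2, "E": 0}
    else:  # class 2 diester
        u1 = np.array([0.0, 0.0, 1.0])
        u2 = _cone(u1, r["angle"], 0.0)
        o3 = r["d_o3"] * u1
        o5 = r["d_o5"] * u2
        records.append(Atom("O", tuple(o3), serial, name="O3'")); serial += 1
        records.append(Atom("O", tuple(o5), serial, name="O5'")); serial += 1
        bis = _unit(u1 + u2)
        n = _unit(np.cross(u1, u2))  # normal of the O3'–E–O5' plane
        v_plus = _unit(-bis + 1.3 * n)
        v_minus = _unit(-bis - 1.3 * n)
        records.append(Atom("O", tuple(r["d_op"] * v_plus), serial, name="Op")); serial += 1
        records.append(Atom("O", tuple(d_term * v_minus), serial, name="Ot1")); serial += 1
        if anionic == "mono":
            pass  # the single non-bridging P–O⁻/As–O⁻ plus P=O: charge −1, no hydroxyl H
        records.extend(_scaffold_atoms(central, "2", o3, e, 135.0, serial, "3"))
        serial += 4
        records.extend(_scaffold_atoms(central, "2", o5, e, 225.0, serial, "5"))
        exact = {central, "O3'", "O5'", "Op"}
        idx = {central: 0, "O3'": 1, "O5'": 2, "Op": 3, "E": 0}
    return records, exact, idx


def make_ideal_ester(central: str, ester_class: str, anionic: str, seed: int) -> FixtureBundle:
    """Tetrahedral ester reactant at published bond lengths/angles.

    The centre, the bridging oxygen(s) and O_p are placed exactly; scaffold
    and hydrogen coordinates carry the ±0.01 Å jitter.
    """
    _check_enums(central, ester_class, anionic)
    rng = np.random.default_rng(seed)
    records, exact, idx = _reactant_records(central, ester_class, anionic)
    charge = -1 if anionic == "mono" else -2
    label = f"{central}-{ester_class}-{anionic}anionic reactant"
    geom = _assemble(records, charge, label, "reactant", rng, exact)
    t = ESTER_GEOMETRY_TARGETS[(central, ester_class, anionic)]["reactant"]
    gt = {
        "ester_class": ester_class,
        "ester_type": "monoester" if ester_class in ("1A", "1B") else "diester",
        "central_atom": central,
        "anionic_state": anionic,
        "charge": charge,
    }
    if ester_class in ("1A", "1B"):
        gt["d(E-Obridge)"] = t["d_bridge"]
        gt["d(E-Op)"] = t["d_op"]
        gt["angle(Obridge-E-Op)"] = t["angle"]
    else:
        gt["d(E-O3')"] = t["d_o3"]
        gt["d(E-O5')"] = t["d_o5"]
        gt["d(E-Op)"] = t["d_op"]
        gt["angle(O3'-E-O5')"] = t["angle"]
        gt["d(O3'-O5')"] = _law_of_cosines(t["d_o3"], t["d_o5"], t["angle"])
    return FixtureBundle(
        kind="ester_reactant",
        seed=seed,
        geometry=geom,
        indices={"reactant": idx},
        ground_truth=gt,
    )


def _law_of_cosines(a: float, b: float, gamma_deg: float) -> float:
    g = math.radians(gamma_deg)
    return math.sqrt(a * a + b * b - 2 * a * b * math.cos(g))


def _ts_records(central: str, ester_class: str, anionic: str):
    t = ESTER_GEOMETRY_TARGETS[(central, ester_class, anionic)]
    ts = t["ts"]
    d_term = TERMINAL_EO[central] + 0.02
    d_w = NUCLEOPHILE_EO_TS[central]
    z = np.array([0.0, 0.0, 1.0])
    records = [Atom(central, (0.0, 0.0, 0.0), 1, name=central)]
    serial = 2
    water_serial_start = None
    if ester_class in ("1A", "1B"):
        bridge_name = t["bridge_name"]
        bridge = ts["d_bridge"] * z  # axial leaving-group oxygen
        records.append(Atom("O", tuple(bridge), serial, name=bridge_name)); serial += 1
        records.append(
            Atom("O", tuple(ts["d_op"] * _cone(z, ts["angle"], 0.0)), serial, name="Op")
        ); serial += 1
        term_dirs = [_cone(z, 90.0, 120.0), _cone(z, 90.0, 240.0)]
        term_pos = []
        for k, d in enumerate(term_dirs):
            term_pos.append(d_term * d)
            records.append(Atom("O", tuple(d_term * d), serial, name=f"Ot{k + 1}")); serial += 1
        if anionic == "mono":
            hp = term_pos[0] + 0.96 * term_dirs[0]
            records.append(Atom("H", tuple(hp), serial, name="Hop")); serial += 1
        water_serial_start = serial
        ow = -d_w * z  # axial nucleophile opposite the leaving group
        records.append(Atom("O", tuple(ow), serial, name="Ow")); serial += 1
        for k in range(2):
            hw = ow + 0.96 * _cone(z, 104.5 + 10 * k, 40.0 + 180.0 * k)
            records.append(Atom("H", tuple(hw), serial, name=f"Hw{k + 1}")); serial += 1
        records.extend(_scaffold_atoms(central, ester_class, bridge, np.zeros(3), 180.0, serial, "L"))
        exact = {central, bridge_name, "Op"}
        idx = {central: 0, bridge_name: 1, "Op": 2, "Ow": water_serial_start - 1, "E": 0}
    else:
        o3 = ts["d_o3"] * z
        records.append(Atom("O", tuple(o3), serial, name="O3'")); serial += 1
        o5 = ts["d_o5"] * _cone(z, ts["angle"], 180.0)
        records.append(Atom("O", tuple(o5), serial, name="O5'")); serial += 1
        op = ts["d_op"] * _cone(z, ts["angle_o3_op"], 60.0)
        records.append(Atom("O", tuple(op), serial, name="Op")); serial += 1
        records.append(
            Atom("O", tuple(d_term * _cone(z, 95.0, 300.0)), serial, name="Ot1")
        ); serial += 1
        water_serial_start = serial
        ow = -d_w * z
        records.append(Atom("O", tuple(ow), serial, name="Ow")); serial += 1
        for k in range(2):
            hw = ow + 0.96 * _cone(z, 104.5 + 10 * k, 40.0 + 180.0 * k)
            records.append(Atom("H", tuple(hw), serial, name=f"Hw{k + 1}")); serial += 1
        records.extend(_scaffold_atoms(central, "2", o3, np.zeros(3), 135.0, serial, "3"))
        serial += 4
        records.extend(_scaffold_atoms(central, "2", o5, np.zeros(3), 225.0, serial, "5"))
        exact = {central, "O3'", "O5'", "Op"}
        idx = {central: 0, "O3'": 1, "O5'": 2, "Op": 3, "Ow": water_serial_start - 1, "E": 0}
    return records, exact, idx


def make_ts_like(central: str, ester_class: str, anionic: str, seed: int) -> FixtureBundle:
    """Paired reactant + trigonal-bipyramidal TS-like structure.

    The TS has a 5-coordinate centre with the water oxygen axial, E–O
    distances elongated relative to the paired reactant exactly as published,
    and a frequency set carrying exactly one imaginary mode.  Reactant→TS
    deltas of the primary parameters are stored as ground truth.
    """
    _check_enums(central, ester_class, anionic)
    rng = np.random.default_rng(seed)
    reactant_bundle = make_ideal_ester(central, ester_class, anionic, seed)
    records, exact, idx_ts = _ts_records(central, ester_class, anionic)
    charge = -1 if anionic == "mono" else -2
    ts_geom = _assemble(
        records, charge, f"{central}-{ester_class}-{anionic}anionic TS", "transition_state",
        rng, exact,
    )
    t = ESTER_GEOMETRY_TARGETS[(central, ester_class, anionic)]
    r, s = t["reactant"], t["ts"]
    if ester_class in ("1A", "1B"):
        bn = t["bridge_name"]
        params = [
            {"label": f"d(E-{bn})", "kind": "distance", "roles": [central, bn],
             "reactant": r["d_bridge"], "ts": s["d_bridge"]},
            {"label": "d(E-Op)", "kind": "distance", "roles": [central, "Op"],
             "reactant": r["d_op"], "ts": s["d_op"]},
            {"label": f"angle({bn}-E-Op)", "kind": "angle", "roles": [bn, central, "Op"],
             "reactant": r["angle"], "ts": s["angle"]},
        ]
    else:
        params = [
            {"label": "d(E-O3')", "kind": "distance", "roles": [central, "O3'"],
             "reactant": r["d_o3"], "ts": s["d_o3"]},
            {"label": "d(E-O5')", "kind": "distance", "roles": [central, "O5'"],
             "reactant": r["d_o5"], "ts": s["d_o5"]},
            {"label": "d(O3'-O5')", "kind": "distance", "roles": ["O3'", "O5'"],
             "reactant": _law_of_cosines(r["d_o3"], r["d_o5"], r["angle"]),
             "ts": _law_of_cosines(s["d_o3"], s["d_o5"], s["angle"])},
            {"label": "d(E-Op)", "kind": "distance", "roles": [central, "Op"],
             "reactant": r["d_op"], "ts": s["d_op"]},
            {"label": "angle(O3'-E-O5')", "kind": "angle",
             "roles": ["O3'", central, "O5'"], "reactant": r["angle"], "ts": s["angle"]},
        ]
    for p in params:
        p["delta"] = p["ts"] - p["reactant"]
    n_modes_r = max(3 * len(reactant_bundle.geometry) - 6, 1)
    n_modes_ts = max(3 * len(ts_geom) - 7, 1)
    freq_r = FrequencySet(tuple(np.sort(rng.uniform(250.0, 3400.0, n_modes_r))))
    imag = -float(rng.uniform(350.0, 600.0))
    freq_ts = FrequencySet(
        (imag, *np.sort(rng.uniform(250.0, 3400.0, n_modes_ts))), is_ts=True
    )
    gt = dict(reactant_bundle.ground_truth)
    gt["parameters"] = params
    return FixtureBundle(
        kind="ester_ts_pair",
        seed=seed,
        geometry=reactant_bundle.geometry,
        ts_geometry=ts_geom,
        frequencies={"reactant": freq_r, "ts": freq_ts},
        indices={"reactant": reactant_bundle.indices["reactant"], "ts": idx_ts},
        ground_truth=gt,
    )


def _check_enums(central, ester_class, anionic):
    if (central, ester_class, anionic) not in ESTER_GEOMETRY_TARGETS:
        raise ValueError(
            f"no geometry targets for central={central!r}, class={ester_class!r}, "
            f"anionic={anionic!r}"
        )


# ---------------------------------------------------------------------------
# fragment energies (activation-strain ground truth)
# ---------------------------------------------------------------------------

def make_fragment_energies(
    target_distortion: float,
    target_interaction: float,
    n_fragments: int = 2,
    seed: int = 0,
) -> FixtureBundle:
    """FragmentEnergies whose decomposition recovers the targets bit-exactly.

    Targets are quantised to the 2⁻²⁰ kcal/mol grid; equilibrium energies are
    integer-valued and every derived energy stays on the grid, so all
    downstream sums and differences are exact in double precision.
    """
    if n_fragments < 2:
        raise ValueError("need at least 2 fragments")
    rng = np.random.default_rng(seed)
    t_dist = _quantize(float(target_distortion))
    t_int = _quantize(float(target_interaction))
    eq = [float(rng.integers(-200, -50)) for _ in range(n_fragments)]
    weights = rng.random(n_fragments)
    weights /= weights.sum()
    dists = [_quantize(t_dist * w) for w in weights[:-1]]
    last = t_dist
    for d in dists:
        last -= d  # exact: all grid numbers well within the mantissa
    dists.append(last)
    labels = ["ester", "water"] + [f"frag{k}" for k in range(3, n_fragments + 1)]
    frags = tuple(
        (labels[k], eq[k] + dists[k], eq[k]) for k in range(n_fragments)
    )
    ts_sum = 0.0
    for _, a, _ in frags:
        ts_sum += a
    fe = FragmentEnergies(
        e_supersystem_ts=ts_sum + t_int,
        fragments=frags,
        reference_note="",
    )
    return FixtureBundle(
        kind="fragment_energies",
        seed=seed,
        fragment_energies=fe,
        ground_truth={
            "distortion": t_dist,
            "interaction": t_int,
            "activation": t_dist + t_int,
            "per_fragment_distortion": {labels[k]: dists[k] for k in range(n_fragments)},
        },
    )


# ---------------------------------------------------------------------------
# thermo species (ΔG‡ ground truth through the RRHO → Eyring path)
# ---------------------------------------------------------------------------

def _rrho_gibbs_closed_form(geometry: Geometry, wavenumbers, temperature: float) -> float:
    """Independent closed-form RRHO Gibbs correction, kcal/mol.

    Textbook partition-function formulas evaluated directly in SI and
    converted once at the end; deliberately written without reference to
    `esterkin.thermochem` so the two can check each other.
    """
    T = temperature
    kB, h, NA, atm = _sc.k, _sc.h, _sc.N_A, _sc.atm
    masses = geometry.masses()
    m_kg = masses.sum() * _sc.atomic_mass
    coords = geometry.coords

    q_t = (2.0 * np.pi * m_kg * kB * T / h**2) ** 1.5 * (kB * T / atm)
    S = _sc.R * (np.log(q_t) + 2.5)
    U = 1.5 * _sc.R * T

    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    x = coords - com
    inertia = np.einsum("k,ij->ij", masses, np.zeros((3, 3)))
    inertia = np.diag([np.sum(masses * (x[:, 1] ** 2 + x[:, 2] ** 2)),
                       np.sum(masses * (x[:, 0] ** 2 + x[:, 2] ** 2)),
                       np.sum(masses * (x[:, 0] ** 2 + x[:, 1] ** 2))])
    off = -np.array([
        [0.0, np.sum(masses * x[:, 0] * x[:, 1]), np.sum(masses * x[:, 0] * x[:, 2])],
        [0.0, 0.0, np.sum(masses * x[:, 1] * x[:, 2])],
        [0.0, 0.0, 0.0],
    ])
    tensor = inertia + off + off.T
    moments = np.sort(np.linalg.eigvalsh(tensor)) * _sc.atomic_mass * 1e-20  # kg m²
    nz = moments[moments > 1e-6 * _sc.atomic_mass * 1e-20]
    if len(geometry) == 1 or len(nz) == 0:
        pass
    elif moments[0] < 1e-6 * _sc.atomic_mass * 1e-20:
        theta = h**2 / (8.0 * np.pi**2 * nz[-1] * kB)
        S += _sc.R * (np.log(T / theta) + 1.0)
        U += _sc.R * T
    else:
        thetas = h**2 / (8.0 * np.pi**2 * moments * kB)
        S += _sc.R * (np.log(np.sqrt(np.pi) * np.sqrt(T**3 / np.prod(thetas))) + 1.5)
        U += 1.5 * _sc.R * T

    nus = np.array([w for w in wavenumbers if w > 0], dtype=float)
    if nus.size:
        theta_v = h * _sc.c * 100.0 * nus / kB
        U += _sc.R * np.sum(theta_v * (0.5 + 1.0 / np.expm1(theta_v / T)))
        S += _sc.R * np.sum(
            (theta_v / T) / np.expm1(theta_v / T) - np.log1p(-np.exp(-theta_v / T))
        )

    H = U + _sc.R * T
    G = H - T * S
    return float(G / (_sc.calorie * 1000.0))


def make_thermo_species(target_dg_act: float, temperature: float, seed: int) -> FixtureBundle:
    """Reactant (ester + water) and TS species whose ΔG‡ equals the target.

    Frequencies and geometries are drawn randomly; the TS electronic energy is
    then solved from the closed-form Gibbs corrections so the analysis path
    (RRHO corrections → activation free energy → Eyring) recovers
    `target_dg_act` to ≲1e-9 kcal/mol.
    """
    rng = np.random.default_rng(seed)
    ts_pair = make_ts_like("As", "1B", "di", seed)
    ester, ts_geom = ts_pair.geometry, ts_pair.ts_geometry

    water = Geometry(
        [
            Atom("O", (0.0, 0.0, 0.0), 1, name="Ow"),
            Atom("H", (0.9572, 0.0, 0.0), 2, name="Hw1"),
            Atom("H", (-0.2400, 0.9266, 0.0), 3, name="Hw2"),
        ],
        charge=0,
        label="water",
        role="fragment",
    )
    freq_ester = FrequencySet(tuple(np.sort(rng.uniform(250.0, 3300.0, 3 * len(ester) - 6))))
    freq_water = FrequencySet((1602.5, 3650.1, 3755.8))
    freq_ts = FrequencySet(
        (-float(rng.uniform(350.0, 600.0)),
         *np.sort(rng.uniform(250.0, 3300.0, 3 * len(ts_geom) - 7))),
        is_ts=True,
    )
    g_ester = _rrho_gibbs_closed_form(ester, freq_ester.wavenumbers, temperature)
    g_water = _rrho_gibbs_closed_form(water, freq_water.wavenumbers, temperature)
    g_ts = _rrho_gibbs_closed_form(ts_geom, freq_ts.wavenumbers, temperature)

    e_ester = float(rng.integers(-150000, -100000))
    e_water = float(rng.integers(-50000, -40000))
    target = float(target_dg_act)
    e_ts = target + (e_ester + g_ester) + (e_water + g_water) - g_ts

    return FixtureBundle(
        kind="thermo_species",
        seed=seed,
        geometry=ester,
        ts_geometry=ts_geom,
        extra_geometries={"water": water},
        frequencies={"ester": freq_ester, "water": freq_water, "ts": freq_ts},
        electronic_energies={"ester": e_ester, "water": e_water, "ts": e_ts},
        ground_truth={"dg_act": target, "temperature": temperature},
    )


# ---------------------------------------------------------------------------
# mock sugar–phosphate strands
# ---------------------------------------------------------------------------

_RES_NAME_CYCLE = ("DT", "DT", "DA", "DA")

# backbone bond lengths, Å
_B_OC = 1.43
_B_CC = 1.53
_B_PO = {"P": 1.60, "As": 1.71}
_B_PO_TERM = {"P": 1.48, "As": 1.60}
_ZIGZAG_HALF = 35.26  # deg off the chain axis → 109.47° backbone angles


def make_mock_strand(n_residues: int, central_elements=None, seed: int = 0) -> FixtureBundle:
    """Simplified single-stranded sugar–phosphate model with valid PDB metadata.

    Each residue carries a minimal sp³ sugar fragment
    (O5′–C5′–C4′(–C1′–N)–C3′–O3′ with explicit hydrogens) and residues are
    joined by bridging P/As centres bearing two free oxygens.  Backbone
    connectivity (and therefore the QM/MM cut rule's distance bookkeeping) is
    correct by construction and recorded as declared bond edges.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    if central_elements is None:
        central_elements = ["P"] * (n_residues - 1)
    central_elements = list(central_elements)
    if len(central_elements) != n_residues - 1:
        raise ValueError("need one bridging centre per inter-residue linkage")
    for el in central_elements:
        if el not in ("P", "As"):
            raise ValueError(f"bridging centre must be P or As, got {el!r}")
    rng = np.random.default_rng(seed)

    atoms: list[Atom] = []
    edges: list[tuple[int, int]] = []
    serial = 1
    pos = np.zeros(3)
    direction_up = True
    center_indices: list[int] = []
    per_residue_counts: list[int] = []

    def step(bond: float) -> np.ndarray:
        nonlocal pos, direction_up
        a = math.radians(_ZIGZAG_HALF)
        d = np.array([math.cos(a), math.sin(a) if direction_up else -math.sin(a), 0.0])
        direction_up = not direction_up
        pos = pos + bond * d
        return pos.copy()

    def add(el, p, name, res_name, res_num) -> int:
        nonlocal serial
        atoms.append(
            Atom(el, tuple(p), serial, name=name, residue_name=res_name,
                 residue_number=res_num, chain_id="A")
        )
        serial += 1
        return len(atoms) - 1

    up = np.array([0.0, 0.0, 1.0])
    prev_o3: int | None = None
    for res in range(1, n_residues + 1):
        res_name = _RES_NAME_CYCLE[(res - 1) % len(_RES_NAME_CYCLE)]
        count0 = len(atoms)
        if res > 1:
            el = central_elements[res - 2]
            p_pos = step(_B_PO[el])
            i_p = add(el, p_pos, el if el == "P" else "AS", res_name, res)
            center_indices.append(i_p)
            edges.append((prev_o3, i_p))
            i_o1 = add("O", p_pos + _B_PO_TERM[el] * up, "OP1", res_name, res)
            i_o2 = add("O", p_pos - _B_PO_TERM[el] * up, "OP2", res_name, res)
            edges.extend([(i_p, i_o1), (i_p, i_o2)])
            o5_pos = step(_B_PO[el])
            i_o5 = add("O", o5_pos, "O5'", res_name, res)
            edges.append((i_p, i_o5))
        else:
            i_o5 = add("O", pos.copy(), "O5'", res_name, res)
        c5_pos = step(_B_OC)
        i_c5 = add("C", c5_pos, "C5'", res_name, res)
        edges.append((i_o5, i_c5))
        i_h = add("H", c5_pos + 1.09 * up, "H5'1", res_name, res)
        edges.append((i_c5, i_h))
        i_h = add("H", c5_pos - 1.09 * up, "H5'2", res_name, res)
        edges.append((i_c5, i_h))
        c4_pos = step(_B_CC)
        i_c4 = add("C", c4_pos, "C4'", res_name, res)
        edges.append((i_c5, i_c4))
        i_h = add("H", c4_pos - 1.09 * up, "H4'", res_name, res)
        edges.append((i_c4, i_h))
        c1_pos = c4_pos + 1.54 * up
        i_c1 = add("C", c1_pos, "C1'", res_name, res)
        edges.append((i_c4, i_c1))
        i_h = add("H", c1_pos + 1.09 * np.array([0.0, 1.0, 0.0]), "H1'1", res_name, res)
        edges.append((i_c1, i_h))
        i_h = add("H", c1_pos - 1.09 * np.array([0.0, 1.0, 0.0]), "H1'2", res_name, res)
        edges.append((i_c1, i_h))
        i_n = add("N", c1_pos + 1.47 * up, "N1", res_name, res)
        edges.append((i_c1, i_n))
        c3_pos = step(_B_CC)
        i_c3 = add("C", c3_pos, "C3'", res_name, res)
        edges.append((i_c4, i_c3))
        i_h = add("H", c3_pos + 1.09 * up, "H3'1", res_name, res)
        edges.append((i_c3, i_h))
        i_h = add("H", c3_pos - 1.09 * up, "H3'2", res_name, res)
        edges.append((i_c3, i_h))
        o3_pos = step(_B_OC)
        i_o3 = add("O", o3_pos, "O3'", res_name, res)
        edges.append((i_c3, i_o3))
        prev_o3 = i_o3
        per_residue_counts.append(len(atoms) - count0)

    jittered = [
        Atom(a.element,
             tuple(np.array(a.coordinates) + rng.uniform(-JITTER, JITTER, 3)),
             a.serial, a.name, a.residue_name, a.residue_number, a.chain_id)
        for a in atoms
    ]
    geom = Geometry(jittered, charge=-(n_residues - 1), label="mock strand", role="reactant")
    return FixtureBundle(
        kind="strand",
        seed=seed,
        geometry=geom,
        bond_edges=edges,
        ground_truth={
            "n_atoms": len(atoms),
            "per_residue_counts": per_residue_counts,
            "n_backbone_centers": len(center_indices),
            "backbone_center_indices": center_indices,
            "central_elements": central_elements,
        },
    )
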