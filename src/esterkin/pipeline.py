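"""Per-species orchestration and the comparative stability report.

`run_species` composes the other modules for one ester species: classify the
structure if one is given, measure the reactant/TS parameter table, decompose
the barrier if fragment energies are present, and obtain the rate constant —
either forward from a supplied or thermochemistry-derived ΔG‡, or backward
from a supplied rate.  `build_report` groups the records into the comparative
As-versus-P table with pairwise and cross-ester stability ratios.

Every number a rendered report shows is read off a `SpeciesRecord` field; the
renderer performs no computation of its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

from .asm import ASMResult, decompose
from .errors import ConsistencyError, EsterkinError
from .geometry_analysis import GeometryTable, parameter_table
from .io_structures import Geometry, perceive_bonds, read_pdb_subset, read_xyz
from .kinetics import RateResult, eyring_rate, format_sci, invert_eyring, stability_ratio
from .model_builder import EsterClassification, classify_ester
from .thermochem import activation_free_energy, rrho_corrections

logger = logging.getLogger("esterkin")

__all__ = ["SpeciesRecord", "StabilityReport", "run_species", "build_report"]

DEFAULT_TEMPERATURE = 298.0  # K
DEFAULT_CONSISTENCY_TOL = 0.05  # kcal/mol slack between a supplied k and ΔG‡


@dataclass
class SpeciesRecord:
    """Assembled per-species results: one row of the comparative rate table."""

    label: str
    dg_act: float
    rate: RateResult
    classification: EsterClassification | None = None
    geometry_table: GeometryTable | None = None
    asm_result: ASMResult | None = None
    ester_class: str | None = None
    central_atom: str | None = None
    anionic_state: str | None = None
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def group_key(self) -> tuple[str, str]:
        return (self.ester_class or "?", self.anionic_state or "?")


def _entry_hash(entry: dict) -> str:
    try:
        blob = json.dumps(
            {k: v for k, v in entry.items() if isinstance(v, (str, int, float, bool, type(None)))},
            sort_keys=True,
        )
    except TypeError:
        blob = repr(sorted(entry))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_geometry(entry: dict, key: str) -> Geometry | None:
    if f"{key}_geometry" in entry:
        return entry[f"{key}_geometry"]
    path = entry.get(f"{key}_file")
    if path is None:
        return None
    with open(path) as fh:
        text = fh.read()
    charge = int(entry.get("charge", 0))
    if str(path).lower().endswith(".pdb"):
        return read_pdb_subset(text, charge=charge, role=key if key != "ts" else "transition_state")
    return read_xyz(text, charge=charge, role=key if key != "ts" else "transition_state")


def run_species(entry: dict) -> SpeciesRecord:
    """Fill every derivable field of a species record from one config entry.

    Recognised keys: ``label``; ``temperature`` (K, default 298); ``c_std``;
    structure input ``reactant_geometry``/``reactant_file`` and
    ``ts_geometry``/``ts_file`` with ``charge``; ``param_specs`` for the
    geometry table; ``fragment_energies`` (+ optional
    ``reactant_reference_energy``); and exactly one rate source —
    ``dg_act`` (kcal/mol), ``rate_constant`` (s⁻¹), or
    ``energies`` = {reactant: [(E_elec, FrequencySet, Geometry), ...],
    ts: (E_elec, FrequencySet, Geometry)}.  Missing optional inputs yield
    explicitly-None fields.
    """
    label = entry.get("label", "species")
    temperature = float(entry.get("temperature", DEFAULT_TEMPERATURE))
    c_std = float(entry.get("c_std", 1.0))
    tol = float(entry.get("consistency_tol_kcal", DEFAULT_CONSISTENCY_TOL))
    warnings_log: list[str] = []
    logger.info("run_species %s [%s]", label, _entry_hash(entry))

    reactant = _load_geometry(entry, "reactant")
    ts = _load_geometry(entry, "ts")

    classification = None
    if reactant is not None:
        try:
            bg = entry.get("bondgraph") or perceive_bonds(reactant)
            classification = classify_ester(reactant, bg)
            if classification.center_ambiguous:
                warnings_log.append("reaction centre ambiguous (tie broken by serial)")
        except EsterkinError as exc:
            warnings_log.append(f"classification failed: {exc}")

    geometry_table = None
    if reactant is not None and ts is not None and entry.get("param_specs"):
        geometry_table = parameter_table(reactant, ts, entry["param_specs"])

    asm_result = None
    if entry.get("fragment_energies") is not None:
        asm_result = decompose(
            entry["fragment_energies"], entry.get("reactant_reference_energy")
        )

    # --- rate source
    dg_given = entry.get("dg_act")
    k_given = entry.get("rate_constant")
    energies = entry.get("energies")
    dg_act: float
    if energies is not None:
        g_react = 0.0
        for e_elec, freqs, geom in energies["reactant"]:
            g_react += e_elec + rrho_corrections(geom, freqs, temperature).gibbs_correction
        e_ts, f_ts, g_ts_geom = energies["ts"]
        g_ts = e_ts + rrho_corrections(g_ts_geom, f_ts, temperature).gibbs_correction
        dg_act = activation_free_energy(g_react, g_ts)
        if dg_given is not None and abs(float(dg_given) - dg_act) > tol:
            raise ConsistencyError(
                f"{label}: supplied ΔG‡ {dg_given} vs thermochemistry-derived "
                f"{dg_act:.4f} kcal/mol"
            )
    elif dg_given is not None:
        dg_act = float(dg_given)
        if k_given is not None:
            dg_from_k = invert_eyring(float(k_given), temperature, c_std)
            if abs(dg_from_k - dg_act) > tol:
                raise ConsistencyError(
                    f"{label}: rate {k_given} s⁻¹ implies ΔG‡ {dg_from_k:.4f} kcal/mol, "
                    f"inconsistent with supplied {dg_act} (tol {tol})"
                )
    elif k_given is not None:
        dg_act = invert_eyring(float(k_given), temperature, c_std)
    else:
        raise EsterkinError(f"{label}: no rate source (dg_act, rate_constant or energies)")
    if dg_act < 0:
        warnings_log.append(f"negative activation free energy ({dg_act:.3f} kcal/mol)")
    rate = eyring_rate(dg_act, temperature, c_std)

    return SpeciesRecord(
        label=label,
        dg_act=dg_act,
        rate=rate,
        classification=classification,
        geometry_table=geometry_table,
        asm_result=asm_result,
        ester_class=(classification.ester_class if classification else entry.get("ester_class")),
        central_atom=(classification.central_atom if classification else entry.get("central_atom")),
        anionic_state=(
            classification.anionic_state if classification else entry.get("anionic_state")
        ),
        provenance={
            "config_hash": _entry_hash(entry),
            "reactant_file": entry.get("reactant_file"),
            "ts_file": entry.get("ts_file"),
            "seed": entry.get("seed"),
            "temperature": temperature,
            "c_std": c_std,
        },
        warnings=warnings_log,
    )


@dataclass
class StabilityReport:
    """Comparative stability table: grouped records, ratios, ranking."""

    records: list[SpeciesRecord]
    as_p_ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    cross_ester_ratios: dict[str, dict[str, float]] = field(default_factory=dict)
    ranking: list[str] = field(default_factory=list)
    footer_warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "records": [
                {
                    "label": r.label,
                    "ester_class": r.ester_class,
                    "central_atom": r.central_atom,
                    "anionic_state": r.anionic_state,
                    "dg_act_kcal_mol": r.dg_act,
                    "rate_constant_s": r.rate.rate_constant,
                    "half_life_s": r.rate.half_life,
                    "distortion": r.asm_result.distortion if r.asm_result else None,
                    "interaction": r.asm_result.interaction if r.asm_result else None,
                    "activation": r.asm_result.activation if r.asm_result else None,
                }
                for r in self.records
            ],
            "as_vs_p_stability_ratios": {
                f"class {c} / {a}anionic": v for (c, a), v in self.as_p_ratios.items()
            },
            "cross_ester_stability_ratios": self.cross_ester_ratios,
            "ranking_most_stable_first": self.ranking,
            "warnings": self.footer_warnings,
        }
        return json.dumps(payload, indent=2)

    def to_tsv(self) -> str:
        lines = ["label\tclass\tcentral\tanion\tdG_act_kcal_mol\tk_s-1\thalf_life_s"]
        for r in self.records:
            lines.append(
                f"{r.label}\t{r.ester_class or '-'}\t{r.central_atom or '-'}\t"
                f"{r.anionic_state or '-'}\t{r.dg_act:.2f}\t"
                f"{format_sci(r.rate.rate_constant)}\t{format_sci(r.rate.half_life)}"
            )
        if self.as_p_ratios:
            lines.append("")
            lines.append("# As/P stability ratios (k_As / k_P) per (class, anion)")
            for (c, a), v in sorted(self.as_p_ratios.items()):
                lines.append(f"# class {c}, {a}anionic:\t{format_sci(v)}")
        for w in self.footer_warnings:
            lines.append(f"# warning: {w}")
        return "\n".join(lines) + "\n"


def _canonical_sort(records):
    order_class = {"1A": 0, "1B": 1, "2": 2}
    order_anion = {"mono": 0, "di": 1}
    order_central = {"As": 0, "P": 1}
    return sorted(
        records,
        key=lambda r: (
            order_class.get(r.ester_class, 99),
            order_anion.get(r.anionic_state, 99),
            order_central.get(r.central_atom, 99),
            r.label,
        ),
    )


def build_report(records) -> StabilityReport:
    """Group records, compute As/P and monoester/diester stability ratios."""
    records = _canonical_sort(list(records))
    if not records:
        raise EsterkinError("report needs at least one species record")

    by_cell: dict[tuple[str, str, str], SpeciesRecord] = {}
    for r in records:
        if r.ester_class and r.central_atom and r.anionic_state:
            by_cell.setdefault((r.ester_class, r.central_atom, r.anionic_state), r)

    as_p_ratios = {}
    for (cls, central, anion), rec in by_cell.items():
        if central != "P":
            continue
        partner = by_cell.get((cls, "As", anion))
        if partner is not None:
            # P hydrolyses slower ⇒ ratio = k_As / k_P ≥ 1 quantifies P's advantage
            as_p_ratios[(cls, anion)] = stability_ratio(
                rec.rate.rate_constant, partner.rate.rate_constant
            )

    cross: dict[str, dict[str, float]] = {}
    for central in ("As", "P"):
        diester = by_cell.get(("2", central, "mono"))
        if diester is None:
            continue
        entry = {}
        for cls in ("1A", "1B"):
            mono_di = by_cell.get((cls, central, "di"))
            if mono_di is not None:
                entry[f"diester-mono vs class {cls} di"] = stability_ratio(
                    diester.rate.rate_constant, mono_di.rate.rate_constant
                )
        if entry:
            cross[central] = entry

    ranking = [
        r.label for r in sorted(records, key=lambda r: r.rate.log_rate)
    ]  # most stable (slowest) first
    footer = [w for r in records for w in r.warnings]
    return StabilityReport(
        records=records,
        as_p_ratios=as_p_ratios,
        cross_ester_ratios=cross,
        ranking=ranking,
        footer_warnings=footer,
    )
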