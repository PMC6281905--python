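"""Published reference values used as analysis inputs.

`REFERENCE_RATES` holds the published first-order hydrolysis rate constants
(s⁻¹, 298 K, aqueous continuum) for the arsenate/phosphate ester species the
pipeline models, together with the number of significant figures each value
was printed at.  They are inputs to round-trip, ratio and report operations —
the package never computes them ab initio (the electronic-structure step is
out of scope).

`ESTER_GEOMETRY_TARGETS` carries the published bond lengths (Å) and bond
angles (deg) of the optimised reactant (R) and transition-state (TS)
structures for each (central atom, ester class, anionic state) combination;
the synthetic-structure generator places atoms at exactly these values.
"""

from __future__ import annotations

#: experimental non-enzymatic pyroarsenate hydrolysis rate, s⁻¹, 298 K
EXPERIMENTAL_PYROARSENATE_RATE = 0.05

#: published rate constants: (class, central, anionic) -> (k in s⁻¹, printed sig figs)
REFERENCE_RATES: dict[tuple[str, str, str], tuple[float, int]] = {
    ("1A", "As", "mono"): (0.0003, 1),
    ("1A", "P", "mono"): (5.49e-16, 3),
    ("1A", "As", "di"): (0.08, 1),
    ("1A", "P", "di"): (3.17e-15, 3),
    ("1B", "As", "mono"): (0.0007, 1),
    ("1B", "P", "mono"): (1.58e-16, 3),
    ("1B", "As", "di"): (0.07, 1),
    ("1B", "P", "di"): (8.53e-14, 3),
    ("2", "As", "mono"): (1.23e-6, 3),
    ("2", "P", "mono"): (5.74e-20, 3),
}

SPECIES_NAMES: dict[tuple[str, str], str] = {
    ("1A", "As"): "pyroarsenate",
    ("1A", "P"): "pyrophosphate",
    ("1B", "As"): "ribose-1-arsenate",
    ("1B", "P"): "ribose-1-phosphate",
    ("2", "As"): "arsenodiester-DNA",
    ("2", "P"): "phosphodiester-DNA",
}

#: published R/TS geometry values for mono-/diesters.
#: For classes 1A/1B: d_bridge = d(E–O_L) / d(E–O1′), d_op = d(E–O_p),
#: angle = ∠(bridge–E–O_p).  For class 2: d_o3/d_o5 = d(E–O3′)/d(E–O5′),
#: d_op = d(E–O_p), angle = ∠(O3′–E–O5′).
ESTER_GEOMETRY_TARGETS: dict[tuple[str, str, str], dict] = {
    ("P", "1A", "mono"): {
        "bridge_name": "OL",
        "reactant": {"d_bridge": 1.64, "d_op": 1.48, "angle": 108.27},
        "ts": {"d_bridge": 1.68, "d_op": 1.58, "angle": 93.39},
    },
    ("As", "1A", "mono"): {
        "bridge_name": "OL",
        "reactant": {"d_bridge": 1.76, "d_op": 1.63, "angle": 109.65},
        "ts": {"d_bridge": 1.77, "d_op": 1.70, "angle": 99.13},
    },
    ("P", "1A", "di"): {
        "bridge_name": "OL",
        "reactant": {"d_bridge": 1.70, "d_op": 1.51, "angle": 105.41},
        "ts": {"d_bridge": 1.79, "d_op": 1.65, "angle": 87.03},
    },
    ("As", "1A", "di"): {
        "bridge_name": "OL",
        "reactant": {"d_bridge": 1.81, "d_op": 1.66, "angle": 102.00},
        "ts": {"d_bridge": 1.82, "d_op": 1.75, "angle": 91.63},
    },
    ("P", "1B", "mono"): {
        "bridge_name": "O1'",
        "reactant": {"d_bridge": 1.63, "d_op": 1.48, "angle": 106.08},
        "ts": {"d_bridge": 1.67, "d_op": 1.57, "angle": 94.10},
    },
    ("As", "1B", "mono"): {
        "bridge_name": "O1'",
        "reactant": {"d_bridge": 1.76, "d_op": 1.62, "angle": 106.59},
        "ts": {"d_bridge": 1.79, "d_op": 1.69, "angle": 95.64},
    },
    ("P", "1B", "di"): {
        "bridge_name": "O1'",
        "reactant": {"d_bridge": 1.70, "d_op": 1.50, "angle": 101.76},
        "ts": {"d_bridge": 1.74, "d_op": 1.62, "angle": 87.07},
    },
    ("As", "1B", "di"): {
        "bridge_name": "O1'",
        "reactant": {"d_bridge": 1.80, "d_op": 1.65, "angle": 102.72},
        "ts": {"d_bridge": 1.81, "d_op": 1.73, "angle": 90.44},
    },
    ("P", "2", "mono"): {
        "reactant": {"d_o3": 1.64, "d_o5": 1.63, "d_op": 1.48, "angle": 101.00},
        "ts": {"d_o3": 1.67, "d_o5": 1.62, "d_op": 1.59, "angle": 97.33,
               "angle_o3_op": 95.46},
    },
    ("As", "2", "mono"): {
        "reactant": {"d_o3": 1.77, "d_o5": 1.76, "d_op": 1.63, "angle": 100.47},
        "ts": {"d_o3": 1.78, "d_o5": 1.75, "d_op": 1.71, "angle": 97.23,
               "angle_o3_op": 98.58},
    },
}

#: terminal (non-bridging, non-protonated) E–O bond length, Å
TERMINAL_EO = {"P": 1.50, "As": 1.66}
#: distance of the attacking water oxygen from the centre in the TS, Å
NUCLEOPHILE_EO_TS = {"P": 1.90, "As": 2.00}
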