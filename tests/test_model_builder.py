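import numpy as np
import pytest

from _oracles import brute_force_min_qm, classify_pattern_oracle
from esterkin.errors import EsterkinError, SubstitutionError, UnsupportedEsterError
from esterkin.io_structures import Atom, BondGraph, Geometry, perceive_bonds
from esterkin.model_builder import (
    classify_ester,
    extract_strand,
    partition_oniom,
    substitute_central_atoms,
)
from esterkin.synthetic_data import make_ideal_ester, make_mock_strand


def alkyl_phosphate_chain(n_carbons=6):
    """P–O–(CH2)n–CH3 chain with a declared bond graph (linear test case)."""
    atoms = [Atom("P", (0.0, 0.0, 0.0), 1, name="P"), Atom("O", (1.5, 0.0, 0.0), 2)]
    edges = [(0, 1)]
    prev = 1
    idx = 2
    carbon_indices = []
    for c in range(n_carbons):
        x = 3.0 + 1.5 * c
        atoms.append(Atom("C", (x, 0.0, 0.0), idx + 1))
        edges.append((prev, idx))
        carbon_indices.append(idx)
        prev = idx
        idx += 1
        n_h = 3 if c == n_carbons - 1 else 2
        for h in range(n_h):
            atoms.append(Atom("H", (x, 0.9 * (-1) ** h, 0.4 * h), idx + 1))
            edges.append((prev, idx))
            idx += 1
    geom = Geometry(atoms, charge=0)
    return geom, BondGraph.from_edges(len(atoms), edges), carbon_indices


class TestClassifyEster:
    def test_pyro_fixture_is_class_1a_with_ambiguous_center(self):
        b = make_ideal_ester("As", "1A", "di", 1)
        cls = classify_ester(b.geometry, perceive_bonds(b.geometry))
        assert cls.ester_class == "1A"
        assert cls.ester_type == "monoester"
        assert cls.leaving_group_pattern == "O-P-R"
        assert cls.central_atom == "As"
        assert cls.anionic_state == "di"
        assert cls.center_ambiguous  # As and the leaving-group P both carry 4 O

    def test_ribose_like_fixture_is_class_1b(self):
        b = make_ideal_ester("As", "1B", "mono", 1)
        cls = classify_ester(b.geometry, perceive_bonds(b.geometry))
        assert (cls.ester_class, cls.anionic_state) == ("1B", "mono")

    def test_dinucleotide_like_fixture_is_class_2(self):
        b = make_ideal_ester("As", "2", "mono", 1)
        cls = classify_ester(b.geometry, perceive_bonds(b.geometry))
        assert (cls.ester_class, cls.ester_type) == ("2", "diester")

    def test_three_bridges_unsupported(self):
        # orthoester-like: central P with three O–CH3 bridges
        atoms = [Atom("P", (0, 0, 0), 1), Atom("O", (0, 0, 1.6), 2)]
        edges = [(0, 1)]
        idx = 2
        for k in range(3):
            atoms.append(Atom("O", (1.6 * (k + 1), 0, 0), idx + 1))
            edges.append((0, idx))
            atoms.append(Atom("C", (1.6 * (k + 1), 1.4, 0), idx + 2))
            edges.append((idx, idx + 1))
            idx += 2
        g = Geometry(atoms, charge=-1)
        with pytest.raises(UnsupportedEsterError, match="3 bridging"):
            classify_ester(g, BondGraph.from_edges(len(atoms), edges))

    def test_unclassifiable_charge_rejected(self):
        b = make_ideal_ester("P", "1B", "mono", 1)
        neutral = Geometry(b.geometry.atoms, charge=0)
        with pytest.raises(UnsupportedEsterError, match="charge"):
            classify_ester(neutral, perceive_bonds(neutral))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_independent_pattern_oracle(self, ts_bundles, seed):
        from conftest import ALL_SPECIES

        for key in ALL_SPECIES:
            b = make_ideal_ester(*key, seed=seed)
            bg = perceive_bonds(b.geometry)
            got = classify_ester(b.geometry, bg)
            oracle = classify_pattern_oracle(b.geometry, bg)
            assert oracle is not None
            assert got.ester_class == oracle["ester_class"]
            assert got.ester_type == oracle["ester_type"]
            assert got.central_atom == oracle["central_atom"]
            assert got.center_index == oracle["center_index"]


class TestSubstitution:
    def test_empty_positions_identity(self, strand_bundle):
        g = strand_bundle.geometry
        out = substitute_central_atoms(g, [])
        assert out.symbols == g.symbols
        np.testing.assert_array_equal(out.coords, g.coords)

    def test_two_backbone_substitutions(self, strand_bundle):
        g = strand_bundle.geometry
        centers = strand_bundle.ground_truth["backbone_center_indices"]
        out = substitute_central_atoms(g, centers[:2])
        assert len(out) == len(g)
        assert sum(1 for a in out.atoms if a.element == "As") == 2
        assert [a.serial for a in out.atoms] == [a.serial for a in g.atoms]
        # untouched coordinates are bit-exact with adjust_bonds off
        np.testing.assert_array_equal(out.coords, g.coords)

    def test_non_phosphorus_position_rejected(self, strand_bundle):
        with pytest.raises(SubstitutionError):
            substitute_central_atoms(strand_bundle.geometry, [0])  # an O5'

    def test_adjust_bonds_lengthens_each_as_o_bond(self):
        b = make_ideal_ester("P", "1A", "di", 3)
        g = b.geometry
        bg = perceive_bonds(g)
        center = 0
        o_neighbors = [j for j in bg.neighbors(center) if g.symbols[j] == "O"]
        before = {j: np.linalg.norm(g.coords[j] - g.coords[center]) for j in o_neighbors}
        out = substitute_central_atoms(g, [center], adjust_bonds=True, bondgraph=bg)
        for j in o_neighbors:
            after = np.linalg.norm(out.coords[j] - out.coords[center])
            assert after - before[j] == pytest.approx(0.12, abs=1e-6)
        # atoms outside the substituted ester group never move
        moved = {center, *o_neighbors}
        for k in range(len(g)):
            if k not in moved:
                np.testing.assert_array_equal(out.coords[k], g.coords[k])


class TestPartition:
    def test_linear_chain_matches_brute_force(self):
        geom, bg, carbons = alkyl_phosphate_chain(6)
        part = partition_oniom(geom, bg, 0)
        part.validate(geom, bg, 0)
        assert len(part.qm_atoms) == brute_force_min_qm(geom, bg, 0)
        # the first eligible cut is the C–C bond whose both carbons sit >4
        # bonds from the phosphorus
        dist = bg.bfs_distances(0)
        (q, m), = part.cut_bonds
        assert dist[q] == 5 and dist[m] == 6

    def test_no_eligible_bond_everything_qm(self):
        b = make_ideal_ester("As", "1A", "di", 1)  # no sp³ C–C at all
        bg = perceive_bonds(b.geometry)
        with pytest.warns(UserWarning, match="whole system"):
            part = partition_oniom(b.geometry, bg, 0)
        assert part.qm_atoms == frozenset(range(len(b.geometry)))
        assert not part.cut_bonds and not part.link_atoms

    @pytest.mark.parametrize("elements", [["P", "P", "P"], ["As", "As", "P"]])
    def test_strand_invariants_at_every_bridge(self, elements):
        b = make_mock_strand(4, elements, seed=9)
        g = b.geometry
        bg = b.declared_bondgraph()
        for center in b.ground_truth["backbone_center_indices"]:
            part = partition_oniom(g, bg, center)
            part.validate(g, bg, center)
            assert len(part.link_atoms) == len(part.cut_bonds)

    def test_strand_minimality_matches_brute_force(self, strand_bundle):
        g = strand_bundle.geometry
        bg = strand_bundle.declared_bondgraph()
        center = strand_bundle.ground_truth["backbone_center_indices"][1]
        part = partition_oniom(g, bg, center)
        assert len(part.qm_atoms) == brute_force_min_qm(g, bg, center)

    def test_link_atoms_on_cut_axis_at_standard_ch_distance(self, strand_bundle):
        g = strand_bundle.geometry
        bg = strand_bundle.declared_bondgraph()
        center = strand_bundle.ground_truth["backbone_center_indices"][0]
        part = partition_oniom(g, bg, center)
        assert part.cut_bonds
        for q, m, el, pos in part.link_atoms:
            assert el == "H"
            v_link = np.array(pos) - g.coords[q]
            v_bond = g.coords[m] - g.coords[q]
            assert np.linalg.norm(v_link) == pytest.approx(1.09, abs=1e-9)
            cos = v_link @ v_bond / (np.linalg.norm(v_link) * np.linalg.norm(v_bond))
            assert cos == pytest.approx(1.0, abs=1e-12)

    def test_partition_manifest_round_trips(self, strand_bundle):
        import json

        g = strand_bundle.geometry
        bg = strand_bundle.declared_bondgraph()
        center = strand_bundle.ground_truth["backbone_center_indices"][0]
        part = partition_oniom(g, bg, center)
        manifest = json.loads(part.to_manifest())
        assert set(manifest["qm_atoms"]) == part.qm_atoms
        assert manifest["frozen_mm"] is True


class TestExtractStrand:
    def test_full_selection_of_single_residue_is_identity(self):
        b = make_mock_strand(1, [], seed=2)
        out = extract_strand(b.geometry, "A", (1, 1))
        assert len(out) == len(b.geometry)

    def test_residue_window_counts(self, strand_bundle):
        counts = strand_bundle.ground_truth["per_residue_counts"]
        out = extract_strand(strand_bundle.geometry, "A", (1, 2))
        assert len(out) == sum(counts[:2])

    def test_chain_break_raises(self, strand_bundle):
        g = strand_bundle.geometry
        broken = Geometry(
            [a for a in g.atoms if a.residue_number != 2], charge=g.charge
        )
        with pytest.raises(EsterkinError, match="chain break"):
            extract_strand(broken, "A", (1, 4))

    def test_missing_chain_raises(self, strand_bundle):
        with pytest.raises(EsterkinError, match="chain"):
            extract_strand(strand_bundle.geometry, "B", (1, 2))

    def test_cap_termini_adds_hydroxyl_hydrogen(self, strand_bundle):
        counts = strand_bundle.ground_truth["per_residue_counts"]
        plain = extract_strand(strand_bundle.geometry, "A", (2, 3))
        capped = extract_strand(strand_bundle.geometry, "A", (2, 3), cap_termini=True)
        assert len(plain) == sum(counts[1:3])
        # exactly one severed bridging centre beyond the window: O3' of residue 3
        assert len(capped) == len(plain) + 1
        assert capped.atoms[-1].element == "H"
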