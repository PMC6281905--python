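import json

import numpy as np
import pytest

from conftest import ALL_SPECIES
from esterkin import eyring_rate
from esterkin.asm import decompose
from esterkin.geometry_analysis import distance
from esterkin.io_structures import perceive_bonds, read_pdb_subset, read_xyz
from esterkin.model_builder import classify_ester
from esterkin.synthetic_data import (
    make_fragment_energies,
    make_ideal_ester,
    make_mock_strand,
    make_thermo_species,
    make_ts_like,
)
from esterkin.thermochem import activation_free_energy, rrho_corrections


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = make_ts_like("As", "1A", "di", 33)
        b = make_ts_like("As", "1A", "di", 33)
        np.testing.assert_array_equal(a.geometry.coords, b.geometry.coords)
        np.testing.assert_array_equal(a.ts_geometry.coords, b.ts_geometry.coords)
        assert a.frequencies["ts"].wavenumbers == b.frequencies["ts"].wavenumbers

    def test_different_seed_different_jitter(self):
        a = make_ideal_ester("As", "1A", "di", 1)
        b = make_ideal_ester("As", "1A", "di", 2)
        assert not np.array_equal(a.geometry.coords, b.geometry.coords)

    def test_strand_generator_pure(self):
        a = make_mock_strand(3, ["P", "As"], seed=7)
        b = make_mock_strand(3, ["P", "As"], seed=7)
        np.testing.assert_array_equal(a.geometry.coords, b.geometry.coords)
        assert a.bond_edges == b.bond_edges


class TestIdealEster:
    @pytest.mark.parametrize("key", ALL_SPECIES)
    def test_classification_matches_ground_truth(self, key):
        b = make_ideal_ester(*key, seed=5)
        cls = classify_ester(b.geometry, perceive_bonds(b.geometry))
        assert cls.ester_class == b.ground_truth["ester_class"]
        assert cls.central_atom == b.ground_truth["central_atom"]
        assert cls.anionic_state == b.ground_truth["anionic_state"]

    @pytest.mark.parametrize("key", ALL_SPECIES)
    def test_placed_bond_lengths_exact(self, key):
        b = make_ideal_ester(*key, seed=5)
        idx = b.indices["reactant"]
        central = key[0]
        d_op = distance(b.geometry, idx[central], idx["Op"])
        assert d_op == pytest.approx(b.ground_truth["d(E-Op)"], abs=1e-9)

    def test_invalid_enum_rejected(self):
        with pytest.raises(ValueError):
            make_ideal_ester("As", "2", "di", 0)  # diesters are monoanionic only


class TestTsLike:
    def test_elongation_direction_matches_published_trend(self, ts_bundles):
        for key, b in ts_bundles.items():
            params = {p["label"]: p for p in b.ground_truth["parameters"]}
            p = params["d(E-Op)"]
            assert p["ts"] > p["reactant"]

    def test_ts_has_exactly_one_imaginary_mode(self, ts_bundles):
        for b in ts_bundles.values():
            assert sum(1 for w in b.frequencies["ts"].wavenumbers if w < 0) == 1
            assert all(w > 0 for w in b.frequencies["reactant"].wavenumbers)

    def test_five_coordinate_center(self, ts_bundles):
        b = ts_bundles[("P", "2", "mono")]
        bg = perceive_bonds(b.ts_geometry)
        center = b.indices["ts"]["P"]
        o_nbrs = [j for j in bg.neighbors(center) if b.ts_geometry.symbols[j] == "O"]
        assert len(o_nbrs) == 5


class TestFragmentEnergies:
    def test_trivial_zero_targets(self):
        b = make_fragment_energies(0.0, 0.0, 2, 4)
        res = decompose(b.fragment_energies)
        assert (res.distortion, res.interaction, res.activation) == (0.0, 0.0, 0.0)

    def test_cancelling_targets_give_zero_activation(self):
        b = make_fragment_energies(7.0, -7.0, 2, 4)
        assert decompose(b.fragment_energies).activation == 0.0

    def test_recovery_exact_over_many_seeds(self):
        rng = np.random.default_rng(0)
        for seed in range(300):
            t_dist = float(rng.uniform(0, 80))
            t_int = float(rng.uniform(-60, 0))
            n = int(rng.integers(2, 5))
            b = make_fragment_energies(t_dist, t_int, n, seed)
            res = decompose(b.fragment_energies)
            assert res.distortion == b.ground_truth["distortion"]
            assert res.interaction == b.ground_truth["interaction"]
            assert res.activation == b.ground_truth["activation"]
            # quantisation grid stays within 1e-6 of the requested targets
            assert abs(res.distortion - t_dist) < 1e-6


class TestThermoSpecies:
    def test_prescribed_barrier_recovered_through_pipeline(self):
        b = make_thermo_species(18.95, 298.0, 12)
        T = b.ground_truth["temperature"]
        g_react = 0.0
        for name, geom in (("ester", b.geometry), ("water", b.extra_geometries["water"])):
            corr = rrho_corrections(geom, b.frequencies[name], T)
            g_react += b.electronic_energies[name] + corr.gibbs_correction
        g_ts = b.electronic_energies["ts"] + rrho_corrections(
            b.ts_geometry, b.frequencies["ts"], T
        ).gibbs_correction
        dg = activation_free_energy(g_react, g_ts)
        assert dg == pytest.approx(18.95, abs=1e-9)
        # forward Eyring puts the rate at the published pyroarsenate scale
        assert eyring_rate(dg, 298.0).rate_constant == pytest.approx(0.08, abs=0.005)

    def test_zero_barrier_species(self):
        b = make_thermo_species(0.0, 298.0, 3)
        assert b.ground_truth["dg_act"] == 0.0


class TestMockStrand:
    def test_bookkeeping(self, strand_bundle):
        gt = strand_bundle.ground_truth
        assert len(strand_bundle.geometry) == gt["n_atoms"]
        assert sum(gt["per_residue_counts"]) == gt["n_atoms"]
        assert gt["n_backbone_centers"] == 3  # n−1 linkages

    def test_declared_topology_matches_perceived_bonds(self, strand_bundle):
        declared = {tuple(sorted(e)) for e in strand_bundle.bond_edges}
        perceived = set(perceive_bonds(strand_bundle.geometry).edges())
        assert declared == perceived

    def test_arsenic_variant_composition(self):
        b = make_mock_strand(4, ["As", "As", "P"], seed=1)
        assert sum(1 for a in b.geometry.atoms if a.element == "As") == 2
        assert b.geometry.atoms[b.ground_truth["backbone_center_indices"][0]].element == "As"

    def test_pdb_serialization_valid(self, strand_bundle, tmp_path):
        files = strand_bundle.write(str(tmp_path), prefix="strand")
        pdb = next(f for f in files if f.endswith(".pdb"))
        g = read_pdb_subset(open(pdb).read())
        assert len(g) == strand_bundle.ground_truth["n_atoms"]

    def test_wrong_bridge_count_rejected(self):
        with pytest.raises(ValueError):
            make_mock_strand(4, ["P"], seed=0)


class TestBundleSidecar:
    def test_ground_truth_sidecar_serialises(self, tmp_path):
        b = make_ts_like("P", "1B", "mono", 8)
        files = b.write(str(tmp_path))
        sidecar = next(f for f in files if f.endswith("ground_truth.json"))
        data = json.load(open(sidecar))
        assert data["seed"] == 8
        assert data["ground_truth"]["ester_class"] == "1B"
        xyz = next(f for f in files if f.endswith("reactant.xyz"))
        g = read_xyz(open(xyz).read())
        assert len(g) == len(b.geometry)
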