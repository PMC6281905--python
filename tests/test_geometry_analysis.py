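import math

import numpy as np
import pytest

from _oracles import dihedral_atan2, random_rigid_transform
from esterkin.errors import GeometryError
from esterkin.geometry_analysis import (
    ParamSpec,
    angle,
    dihedral,
    distance,
    kabsch_superpose,
    pair_by_residue_atom_name,
    parameter_table,
)
from esterkin.io_structures import Atom, Geometry


def geom_from_coords(coords, element="C"):
    return Geometry(
        [Atom(element, tuple(c), serial=i + 1) for i, c in enumerate(coords)]
    )


class TestMeasurements:
    def test_unit_distance(self):
        g = geom_from_coords([(0, 0, 0), (0, 0, 1)])
        assert distance(g, 0, 1) == pytest.approx(1.0, abs=1e-12)

    def test_distance_against_coordinatewise_arithmetic(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-30, 30, (40, 3))
        g = geom_from_coords(coords)
        for _ in range(100):
            i, j = rng.choice(40, 2, replace=False)
            expected = math.sqrt(sum((coords[i][k] - coords[j][k]) ** 2 for k in range(3)))
            assert abs(distance(g, int(i), int(j)) - expected) < 1e-12

    def test_right_angle(self):
        g = geom_from_coords([(1, 0, 0), (0, 0, 0), (0, 1, 0)])
        assert angle(g, 0, 1, 2) == pytest.approx(90.0, abs=1e-10)

    def test_collinear_angle(self):
        g = geom_from_coords([(1, 0, 0), (0, 0, 0), (-2, 0, 0)])
        assert angle(g, 0, 1, 2) == pytest.approx(180.0, abs=1e-10)

    def test_angle_symmetry(self):
        rng = np.random.default_rng(4)
        g = geom_from_coords(rng.uniform(-5, 5, (3, 3)))
        assert angle(g, 0, 1, 2) == pytest.approx(angle(g, 2, 1, 0), abs=1e-12)

    def test_zero_arm_raises(self):
        g = Geometry(
            [Atom("C", (0, 0, 0), 1), Atom("C", (0, 0, 0), 2), Atom("C", (1, 0, 0), 3)]
        )
        with pytest.raises(GeometryError):
            angle(g, 0, 1, 2)

    def test_planar_cis_and_trans_dihedral(self):
        cis = geom_from_coords([(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, 1, 0)])
        trans = geom_from_coords([(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, -1, 0)])
        assert dihedral(cis, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-10)
        assert abs(dihedral(trans, 0, 1, 2, 3)) == pytest.approx(180.0, abs=1e-10)

    def test_dihedral_against_atan2_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            coords = rng.uniform(-10, 10, (4, 3))
            g = geom_from_coords(coords)
            try:
                got = dihedral(g, 0, 1, 2, 3)
            except GeometryError:
                continue
            assert got == pytest.approx(dihedral_atan2(*coords), abs=1e-9)

    def test_dihedral_reversal_and_mirror_symmetry(self):
        # IUPAC convention: reading the chain from either end gives the same
        # signed torsion; a mirror reflection negates it
        rng = np.random.default_rng(5)
        for _ in range(20):
            coords = rng.uniform(-5, 5, (4, 3))
            g = geom_from_coords(coords)
            d = dihedral(g, 0, 1, 2, 3)
            assert dihedral(g, 3, 2, 1, 0) == pytest.approx(d, abs=1e-10)
            mirrored = geom_from_coords(coords * np.array([1.0, 1.0, -1.0]))
            dm = dihedral(mirrored, 0, 1, 2, 3)
            if abs(abs(d) - 180.0) > 1e-9:
                assert dm == pytest.approx(-d, abs=1e-10)

    def test_all_measurements_rigid_motion_invariant(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(-8, 8, (4, 3))
        g = geom_from_coords(coords)
        d0, a0, t0 = distance(g, 0, 1), angle(g, 0, 1, 2), dihedral(g, 0, 1, 2, 3)
        for _ in range(10):
            q, t = random_rigid_transform(rng)
            gm = g.with_coords(coords @ q.T + t)
            assert distance(gm, 0, 1) == pytest.approx(d0, abs=1e-9)
            assert angle(gm, 0, 1, 2) == pytest.approx(a0, abs=1e-9)
            assert dihedral(gm, 0, 1, 2, 3) == pytest.approx(t0, abs=1e-9)


class TestParameterTable:
    def _specs(self):
        rm = {"reactant": {"a": 0, "b": 1, "c": 2}, "ts": {"a": 0, "b": 1, "c": 2}}
        return [
            ParamSpec("distance", "d(a-b)", ("a", "b"), rm),
            ParamSpec("angle", "ang(a-b-c)", ("a", "b", "c"), rm),
        ]

    def test_identical_geometries_zero_deltas(self):
        g = geom_from_coords([(0, 0, 0), (1.5, 0, 0), (1.5, 1.5, 0)])
        table = parameter_table(g, g, self._specs())
        assert all(row[3] == 0.0 for row in table.rows)

    def test_known_displacement_recovered(self):
        r = geom_from_coords([(0, 0, 0), (1.50, 0, 0), (1.50, 1.50, 0)])
        t = geom_from_coords([(0, 0, 0), (1.65, 0, 0), (1.65, 1.50, 0)])
        table = parameter_table(r, t, self._specs()[:1])
        _, vr, vt, delta = table.rows[0]
        assert (vr, vt) == (pytest.approx(1.50), pytest.approx(1.65))
        assert delta == vt - vr  # exact identity, not approx

    def test_synthetic_pair_deltas_match_ground_truth(self, ts_bundles):
        for bundle in ts_bundles.values():
            table = parameter_table(bundle.geometry, bundle.ts_geometry, bundle.param_specs())
            for (spec, vr, vt, delta), p in zip(
                table.rows, bundle.ground_truth["parameters"]
            ):
                assert vr == pytest.approx(p["reactant"], abs=1e-9), spec.label
                assert vt == pytest.approx(p["ts"], abs=1e-9), spec.label
                assert delta == pytest.approx(p["delta"], abs=1e-9), spec.label

    def test_error_names_offending_spec(self):
        g = geom_from_coords([(0, 0, 0), (0, 0, 0), (1, 0, 0)])
        with pytest.raises(GeometryError, match="ang"):
            parameter_table(g, g, self._specs()[1:])

    def test_tsv_renders_two_decimals(self):
        g = geom_from_coords([(0, 0, 0), (1.234567, 0, 0), (1.2, 1.2, 0)])
        tsv = parameter_table(g, g, self._specs()[:1]).to_tsv()
        assert "1.23" in tsv


class TestKabsch:
    def test_identical_sets_identity(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(-5, 5, (10, 3))
        sup = kabsch_superpose(coords, coords)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_recovers_applied_rotation(self):
        rng = np.random.default_rng(9)
        ref = rng.uniform(-5, 5, (12, 3))
        for _ in range(20):
            q, t = random_rigid_transform(rng)
            mobile = ref @ q.T + t
            sup = kabsch_superpose(ref, mobile)
            assert sup.rmsd < 1e-9
            np.testing.assert_allclose(sup.rotation @ q, np.eye(3), atol=1e-8)
            assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-8

    def test_rotation_always_proper(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            ref = rng.uniform(-5, 5, (6, 3))
            mob = rng.uniform(-5, 5, (6, 3))
            sup = kabsch_superpose(ref, mob)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
            rtr = sup.rotation.T @ sup.rotation
            np.testing.assert_allclose(rtr, np.eye(3), atol=1e-8)

    def test_agrees_with_scipy_align_vectors(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(12)
        ref = rng.uniform(-5, 5, (15, 3))
        mob = ref + rng.normal(0, 0.3, ref.shape)
        sup = kabsch_superpose(ref, mob)
        rot, _ = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        np.testing.assert_allclose(sup.rotation, rot.as_matrix(), atol=1e-6)

    def test_too_few_pairs_raises(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_set_raises(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)

    def test_pairing_helper_excludes_hydrogens(self, strand_bundle):
        g = strand_bundle.geometry
        pairs = pair_by_residue_atom_name(g, g)
        assert pairs  # identical structures pair fully on heavy atoms
        heavies = sum(1 for a in g.atoms if a.element != "H")
        assert len(pairs) == heavies
        assert all(i == j for i, j in pairs)
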