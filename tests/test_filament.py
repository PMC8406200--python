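"""Screw decomposition, filament replication and kink angles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from filadyn.filament import (
    kink_angle,
    replicate_filament,
    screw_decompose,
    unit_transform,
)
from filadyn.structio import (
    DegenerateGeometryError,
    RigidTransform,
    ca_array,
    extract_ca,
)
from filadyn.synthetic import make_helical_fixture, _rotation


def screw_transform(twist_deg, rise, axis=(0, 0, 1), point=(0, 0, 0)):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    point = np.asarray(point, dtype=float)
    rot = Rotation.from_rotvec(np.radians(twist_deg) * axis).as_matrix()
    trans = point - rot @ point + rise * axis
    return RigidTransform(rot, trans)


class TestScrewDecompose:
    def test_forty_degree_fifty_rise(self):
        s = screw_decompose(screw_transform(40.0, 50.0))
        assert s.twist_deg == pytest.approx(40.0, abs=1e-9)
        assert s.rise == pytest.approx(50.0, abs=1e-9)
        assert s.repeats_per_turn == pytest.approx(9.0, abs=1e-9)
        assert s.handedness == +1

    def test_pure_rotation_about_x(self):
        s = screw_decompose(screw_transform(90.0, 0.0, axis=(1, 0, 0)))
        assert s.twist_deg == pytest.approx(90.0, abs=1e-9)
        assert s.rise == pytest.approx(0.0, abs=1e-9)

    def test_offset_axis_recovered(self):
        s = screw_decompose(screw_transform(60.0, 10.0, point=(5.0, -3.0, 2.0)))
        # axis point is reported as the closest point on the axis to origin
        perp = s.axis_point - (s.axis_point @ s.axis) * s.axis
        np.testing.assert_allclose(perp, s.axis_point, atol=1e-9)
        np.testing.assert_allclose(np.cross(s.axis, s.axis_point - np.array([5.0, -3.0, 0.0]))
                                   if False else s.axis, [0, 0, 1], atol=1e-9)

    def test_roundtrip_random_transforms(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            axis = rng.normal(size=3)
            t = screw_transform(rng.uniform(1.0, 179.0), rng.uniform(-30, 30),
                                axis=axis, point=rng.normal(scale=10, size=3))
            s = screw_decompose(t)
            back = s.to_transform()
            np.testing.assert_allclose(back.rotation, t.rotation, atol=1e-6)
            np.testing.assert_allclose(back.translation, t.translation, atol=1e-6)
            assert s.repeats_per_turn * s.twist_deg == pytest.approx(360.0)
            assert s.rise >= 0.0

    def test_handedness_flips_under_mirror(self):
        t = screw_transform(40.0, 50.0)
        s = screw_decompose(t)
        m = np.diag([1.0, 1.0, -1.0])
        mirrored = RigidTransform(m @ t.rotation @ m, m @ t.translation)
        s2 = screw_decompose(mirrored)
        assert s2.handedness == -s.handedness
        assert s2.twist_deg == pytest.approx(s.twist_deg, abs=1e-9)

    def test_handedness_invariant_under_rigid_motion(self):
        t = screw_transform(40.0, 50.0)
        g = RigidTransform(_rotation([1, 2, 0], 33.0), np.array([4.0, 5.0, 6.0]))
        conj = g.compose(t).compose(g.inverse())
        assert screw_decompose(conj).handedness == screw_decompose(t).handedness

    def test_near_identity_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            screw_decompose(RigidTransform(np.eye(3), np.array([0.0, 0, 50.0])))


class TestUnitTransform:
    def test_same_selection_identity(self, helix_fixture):
        structure, truth = helix_fixture
        t, rmsd = unit_transform(structure, truth.unit_chain_sets[0],
                                 truth.unit_chain_sets[0])
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-10)
        assert rmsd == 0.0

    def test_recovers_generating_transform(self, helix_fixture):
        structure, truth = helix_fixture
        t, rmsd = unit_transform(structure, truth.unit_chain_sets[0],
                                 truth.unit_chain_sets[1])
        assert rmsd < 1e-6
        np.testing.assert_allclose(t.rotation, truth.transform.rotation, atol=1e-8)
        s = screw_decompose(t)
        assert s.twist_deg == pytest.approx(truth.twist_deg, abs=1e-6)
        assert s.rise == pytest.approx(truth.rise, abs=1e-6)
        assert s.repeats_per_turn == pytest.approx(9.0, abs=1e-6)

    def test_unequal_pairing_rejected(self, helix_fixture, tetramer_pair):
        structure, truth = helix_fixture
        tet, _ = tetramer_pair
        with pytest.raises(Exception, match="pairing|length"):
            unit_transform(tet, ["A"], ["A", "B"])


class TestReplicateFilament:
    def test_single_copy_is_unit(self, helix_fixture):
        structure, truth = helix_fixture
        unit = structure.subset(truth.unit_chain_sets[0])
        model = replicate_filament(unit, truth.transform, 1)
        assert model.n_units == 1
        np.testing.assert_allclose(model.copies[0].atom_coords(),
                                   unit.atom_coords())

    def test_nine_copies_close_the_turn(self):
        t = screw_transform(40.0, 50.0)
        t9 = t.power(9)
        np.testing.assert_allclose(t9.rotation, np.eye(3), atol=1e-6)

    def test_copies_match_closed_form_screw(self, helix_fixture):
        structure, truth = helix_fixture
        unit = structure.subset(truth.unit_chain_sets[0])
        model = replicate_filament(unit, truth.transform, 5)
        coords0 = unit.atom_coords()
        for k, copy in enumerate(model.copies):
            rot = Rotation.from_euler("z", truth.twist_deg * k, degrees=True).as_matrix()
            expected = coords0 @ rot.T + np.array([0.0, 0.0, truth.rise * k])
            np.testing.assert_allclose(copy.atom_coords(), expected, atol=1e-8)

    def test_total_atoms(self, helix_fixture):
        structure, truth = helix_fixture
        unit = structure.subset(truth.unit_chain_sets[0])
        model = replicate_filament(unit, truth.transform, 4)
        assert sum(c.n_atoms() for c in model.copies) == 4 * unit.n_atoms()

    def test_bad_copy_count(self, helix_fixture):
        structure, truth = helix_fixture
        with pytest.raises(ValueError):
            replicate_filament(structure, truth.transform, 0)


class TestKinkAngle:
    def test_coplanar_duplicate_zero(self, helix_fixture):
        structure, truth = helix_fixture
        # a pure translation copy of unit 0
        from filadyn.structio import Structure
        unit = structure.subset(truth.unit_chain_sets[0])
        shifted = unit.transformed(RigidTransform(np.eye(3), np.array([80.0, 0, 0])))
        merged = Structure(unit.chains + [
            type(c)(c.id + "x", c.residues) for c in shifted.chains])
        angle = kink_angle(merged, [c.id for c in unit.chains],
                           [c.id + "x" for c in shifted.chains])
        assert angle == pytest.approx(0.0, abs=1e-6)

    def test_planted_thirty_degree_kink(self):
        structure, truth = make_helical_fixture(twist=40.0, rise=50.0,
                                                kink=30.0, n=2, seed=5)
        angle = kink_angle(structure, truth.unit_chain_sets[0],
                           truth.unit_chain_sets[1])
        assert angle == pytest.approx(30.0, abs=0.1)

    def test_both_axis_rules_available(self, helix_fixture):
        structure, truth = helix_fixture
        for rule in ("inertia", "plane"):
            a = kink_angle(structure, truth.unit_chain_sets[0],
                           truth.unit_chain_sets[1], rule)
            assert 0.0 <= a <= 90.0
        with pytest.raises(ValueError):
            kink_angle(structure, truth.unit_chain_sets[0],
                       truth.unit_chain_sets[1], "nope")
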