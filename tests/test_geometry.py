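"""Geometric kernel: dihedrals against an independent oracle, posed
pseudotorsions, distances, χ angles, Kabsch recovery and backbone RMSD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from kinoforge import geometry
from kinoforge.errors import DegenerateGeometryError, MissingAtomError


def oracle_dihedral(p1, p2, p3, p4):
    """Independent formulation: project the outer bonds onto the plane
    normal to the central axis and take the signed angle between them."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    axis = p3 - p2
    axis = axis / np.linalg.norm(axis)
    u = (p1 - p2) - np.dot(p1 - p2, axis) * axis
    v = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    angle = math.degrees(math.atan2(np.dot(np.cross(u, v), axis),
                                    np.dot(u, v)))
    return 180.0 if angle == -180.0 else angle


coords = st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50))


class TestDihedral:
    def test_planar_trans_is_180(self):
        assert geometry.dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0),
                                 (1, -1, 0)) == pytest.approx(180.0)

    def test_planar_cis_is_0(self):
        assert geometry.dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0),
                                 (1, 1, 0)) == pytest.approx(0.0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pts = rng.uniform(-10, 10, size=(4, 3))
            try:
                ours = geometry.dihedral(*pts)
            except DegenerateGeometryError:
                continue
            assert abs(ours - oracle_dihedral(*pts)) < 1e-9 \
                or abs(abs(ours) - 180) < 1e-9

    def test_reversal_symmetry_and_mirror_antisymmetry(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-5, 5, size=(4, 3))
        forward = geometry.dihedral(*pts)
        assert geometry.dihedral(*pts[::-1]) == pytest.approx(forward)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert geometry.dihedral(*mirrored) == pytest.approx(-forward)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            geometry.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @settings(max_examples=50, deadline=None)
    @given(axis=coords, angle=st.floats(-179, 179), shift=coords)
    def test_rigid_motion_invariance(self, axis, angle, shift):
        ax = np.asarray(axis)
        if np.linalg.norm(ax) < 1e-3:
            ax = np.array([0.0, 0.0, 1.0])
        rot = Rotation.from_rotvec(np.radians(angle) * ax / np.linalg.norm(ax))
        pts = np.array([[0, 1.2, 0], [0, 0, 0], [1.4, 0, 0], [1.4, -0.8, 0.9]])
        before = geometry.dihedral(*pts)
        after = geometry.dihedral(*(rot.apply(pts) + np.asarray(shift)))
        assert after == pytest.approx(before, abs=1e-6)


class TestDomainFeatures:
    def test_posed_pseudotorsion_recovered(self, config):
        from kinoforge.synthetic_fixtures import ScaffoldParams, make_scaffold
        domain = make_scaffold(ScaffoldParams(
            seed=3, features={"xi_gmotif_p1_p2": -65.0}, min_clearance=0.0),
            config)
        assert geometry.ca_pseudotorsion(domain, 55) == pytest.approx(-65.0,
                                                                      abs=1e-6)

    def test_missing_ca_named_in_error(self, config):
        from kinoforge.synthetic_fixtures import ScaffoldParams, make_scaffold
        domain = make_scaffold(ScaffoldParams(
            seed=3, omit_atoms=((57, "CA"),), min_clearance=0.0), config)
        with pytest.raises(MissingAtomError, match="CA at reference 57"):
            geometry.ca_pseudotorsion(domain, 55)

    def test_backbone_psi_on_ideal_helix(self, default_scaffold):
        # residue 130 sits mid-helix in the scaffold's base fold
        assert geometry.backbone_psi(default_scaffold, 130) == \
            pytest.approx(-47.0, abs=3.0)

    def test_ca_distance_symmetric(self, default_scaffold):
        d_ab = geometry.ca_distance(default_scaffold, 160, 189)
        d_ba = geometry.ca_distance(default_scaffold, 189, 160)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)
        assert geometry.ca_distance(default_scaffold, 100, 100) == 0.0

    def test_min_atom_distance_takes_minimum(self, default_scaffold):
        d_min = geometry.min_atom_distance(default_scaffold, 72, ("NZ",),
                                           91, ("OE1", "OE2"))
        d_oe1 = geometry.min_atom_distance(default_scaffold, 72, ("NZ",),
                                           91, ("OE1",))
        d_oe2 = geometry.min_atom_distance(default_scaffold, 72, ("NZ",),
                                           91, ("OE2",))
        assert d_min == pytest.approx(min(d_oe1, d_oe2), abs=1e-12)

    def test_min_atom_distance_all_absent_errors(self, default_scaffold):
        with pytest.raises(MissingAtomError):
            geometry.min_atom_distance(default_scaffold, 72, ("XX",), 91,
                                       ("OE1",))


class TestSidechainChi:
    def test_posed_chi1(self, config):
        from kinoforge.synthetic_fixtures import ScaffoldParams, make_scaffold
        domain = make_scaffold(ScaffoldParams(
            seed=3, features={"chi_glu": 95.0}, min_clearance=0.0), config)
        glu = domain.residue_by_ref(91)
        assert geometry.sidechain_chi(glu, 1) == pytest.approx(95.0, abs=1e-6)

    def test_posed_chi2_via_helper(self):
        from kinoforge.synthetic_fixtures import _pose_glu_sidechain
        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([1.458, 0.0, 0.0])
        c = ca + np.array([0.5, 1.4, 0.0])
        cb, cg, cd, oe1, oe2 = _pose_glu_sidechain(n, ca, c, 95.0, chi_index=2)
        from kinoforge.structure_model import Atom, Residue
        glu = Residue(1, "GLU")
        for name, coord in [("N", n), ("CA", ca), ("C", c), ("CB", cb),
                            ("CG", cg), ("CD", cd), ("OE1", oe1), ("OE2", oe2)]:
            glu.add_atom(Atom(name, name[0], coord))
        assert geometry.sidechain_chi(glu, 2) == pytest.approx(95.0, abs=1e-6)

    def test_glycine_has_no_chi(self):
        from kinoforge.structure_model import Atom, Residue
        gly = Residue(1, "GLY")
        gly.add_atom(Atom("CA", "C", np.zeros(3)))
        with pytest.raises(MissingAtomError, match="no sidechain chi"):
            geometry.sidechain_chi(gly, 1)


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(-5, 5, size=(10, 3))
        result = geometry.superpose(pts, pts)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(result.transform.rotation, np.eye(3), atol=1e-12)

    def test_known_transform_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, size=(20, 3))
        rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        shift = np.array([1.0, 2.0, 3.0])
        moved = pts @ rot.T + shift
        result = geometry.superpose(moved, pts)
        assert result.rmsd < 1e-8
        recovered = result.transform
        assert np.allclose(recovered.rotation @ rot, np.eye(3), atol=1e-8)
        assert np.allclose(recovered.apply(moved), pts, atol=1e-8)

    def test_agrees_with_scipy_align_vectors(self):
        """Independent oracle: scipy's Kabsch implementation."""
        rng = np.random.default_rng(2)
        a = rng.uniform(-5, 5, size=(15, 3))
        b = rng.uniform(-5, 5, size=(15, 3))
        ours = geometry.superpose(a, b)
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert ours.rmsd == pytest.approx(rssd / math.sqrt(len(a)), abs=1e-8)
        assert np.allclose(ours.transform.rotation, rot.as_matrix(), atol=1e-8)

    def test_reflection_never_returned(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5, 5, size=(12, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        result = geometry.superpose(mirrored, pts)
        assert result.rmsd > 0.1
        assert np.linalg.det(result.transform.rotation) == pytest.approx(1.0,
                                                                         abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(DegenerateGeometryError):
            geometry.superpose(line, line)
        with pytest.raises(DegenerateGeometryError):
            geometry.superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestBackboneRmsd:
    def test_self_is_zero(self, default_scaffold):
        assert geometry.backbone_rmsd(default_scaffold, default_scaffold) == \
            pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_with_fit_is_zero(self, default_scaffold):
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = default_scaffold.transformed(rot, np.array([4.0, -2.0, 1.0]))
        assert geometry.backbone_rmsd(default_scaffold, moved, fit=True) == \
            pytest.approx(0.0, abs=1e-9)

    def test_translation_without_fit_measured(self, default_scaffold):
        moved = default_scaffold.transformed(np.eye(3), np.array([5.0, 0, 0]))
        assert geometry.backbone_rmsd(default_scaffold, moved, fit=False) == \
            pytest.approx(5.0, abs=1e-9)

    def test_incomplete_ids_dropped_and_reported(self, config):
        from kinoforge.synthetic_fixtures import ScaffoldParams, make_scaffold
        a = make_scaffold(ScaffoldParams(seed=3, min_clearance=0.0), config)
        b = make_scaffold(ScaffoldParams(
            seed=3, omit_atoms=((150, "O"),), min_clearance=0.0), config)
        report = geometry.backbone_rmsd_report(a, b)
        assert 150 in report.dropped_ids
        assert 150 not in report.used_ids
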