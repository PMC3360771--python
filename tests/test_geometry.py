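"""Rotations, rigid transforms, centroids and fixed-pairing RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from klapalign.geometry import (
    RigidTransform,
    apply_transform,
    centroid,
    rmsd_of_assignment,
    rotation_matrix,
)

angles = st.floats(-np.pi, np.pi, allow_nan=False)


class TestRotationMatrix:
    def test_zero_angles_is_identity(self):
        assert np.allclose(rotation_matrix([0, 0, 0]), np.eye(3), atol=1e-15)

    def test_quarter_turn_about_z(self):
        R = rotation_matrix([0, 0, np.pi / 2])
        assert np.allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(angles, angles, angles)
    def test_orthonormal_det_plus_one(self, ax, ay, az):
        R = rotation_matrix([ax, ay, az])
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_extrinsic_xyz_composition_order(self):
        theta = [0.3, -0.8, 1.2]
        Rx = rotation_matrix([theta[0], 0, 0])
        Ry = rotation_matrix([0, theta[1], 0])
        Rz = rotation_matrix([0, 0, theta[2]])
        assert np.allclose(rotation_matrix(theta), Rz @ Ry @ Rx, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rotation_matrix([np.nan, 0, 0])


class TestRigidTransform:
    def test_identity_leaves_points(self):
        pts = np.random.default_rng(0).normal(size=(7, 3))
        assert np.allclose(apply_transform(RigidTransform.identity(), pts), pts)

    def test_pure_translation(self):
        t = RigidTransform([1, 0, 0], [0, 0, 0])
        assert np.allclose(apply_transform(t, [[0, 0, 0]]), [[1, 0, 0]])

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(42)
        transform = RigidTransform(rng.normal(size=3) * 10, rng.uniform(-np.pi, np.pi, 3))
        pts = rng.normal(size=(20, 3)) * 5
        back = apply_transform(transform.inverse(), apply_transform(transform, pts))
        assert np.abs(back - pts).max() < 1e-10

    def test_angles_normalized_to_half_open_circle(self):
        t = RigidTransform([0, 0, 0], [3 * np.pi, -3 * np.pi, 0.5])
        assert np.all(t.theta >= -np.pi) and np.all(t.theta < np.pi)
        assert t.theta[2] == pytest.approx(0.5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform([np.inf, 0, 0], [0, 0, 0])

    def test_input_not_mutated(self):
        pts = np.ones((3, 3))
        apply_transform(RigidTransform([1, 2, 3], [0.1, 0.2, 0.3]), pts)
        assert np.all(pts == 1.0)


class TestCentroid:
    def test_single_point(self):
        assert np.allclose(centroid([[1.0, 2.0, 3.0]]), [1, 2, 3])

    def test_two_points(self):
        assert np.allclose(centroid([[0, 0, 0], [2, 0, 0]]), [1, 0, 0])

    def test_centered_cloud_has_origin_centroid(self):
        pts = np.random.default_rng(3).normal(size=(50, 3))
        assert np.abs(centroid(pts - centroid(pts))).max() < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            centroid(np.empty((0, 3)))


class TestRmsdOfAssignment:
    def test_identical_coordinates_zero(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        pairs = [(i, i) for i in range(1, 6)]
        assert rmsd_of_assignment(pts, pts, pairs) == 0.0

    def test_unit_displacements_closed_form(self):
        a = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        b = np.array([[1.0, 0, 0], [5.0, 1.0, 0]])
        assert rmsd_of_assignment(a, b, [(1, 1), (2, 2)]) == pytest.approx(1.0)

    def test_matches_per_term_summation(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        perm = rng.permutation(10)
        pairs = [(i + 1, int(j) + 1) for i, j in enumerate(perm)]
        direct = np.sqrt(sum(np.sum((a[i - 1] - b[j - 1]) ** 2) for i, j in pairs) / 10)
        assert rmsd_of_assignment(a, b, pairs) == pytest.approx(direct, abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(8, 3)) * 4, rng.normal(size=(8, 3)) * 4
        pairs = [(i, i) for i in range(1, 9)]
        motion = RigidTransform(rng.normal(size=3) * 10, rng.uniform(-np.pi, np.pi, 3))
        before = rmsd_of_assignment(a, b, pairs)
        after = rmsd_of_assignment(apply_transform(motion, a), apply_transform(motion, b), pairs)
        assert after == pytest.approx(before, abs=1e-9)

    @pytest.mark.parametrize("pairs", [[], [(1, 1), (1, 2)], [(1, 1), (2, 1)]])
    def test_empty_or_duplicated_pairs_rejected(self, pairs):
        pts = np.zeros((3, 3))
        with pytest.raises(ValueError):
            rmsd_of_assignment(pts, pts, pairs)

    def test_out_of_range_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(IndexError):
            rmsd_of_assignment(pts, pts, [(1, 3)])
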