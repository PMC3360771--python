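"""Cost matrices and the exact k-cardinality assignment solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from klapalign.assignment import Alignment, build_cost_matrix, evaluate_F, solve_klap
from klapalign.geometry import RigidTransform, apply_transform, rmsd_of_assignment


class TestAlignmentType:
    def test_one_to_one_enforced(self):
        with pytest.raises(ValueError):
            Alignment(((1, 1), (1, 2)))
        with pytest.raises(ValueError):
            Alignment(((1, 1), (2, 1)))

    def test_cardinality(self):
        assert Alignment(((1, 2), (2, 3))).k == 2
        assert Alignment(()).k == 0


class TestBuildCostMatrix:
    def test_self_identity_zero_diagonal(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        costs = build_cost_matrix(RigidTransform.identity(), pts, pts)
        assert np.allclose(np.diag(costs), 0.0)

    def test_single_pair_squared_distance(self):
        costs = build_cost_matrix(
            RigidTransform.identity(), np.array([[0.0, 0, 0]]), np.array([[2.0, 0, 0]])
        )
        assert costs.shape == (1, 1)
        assert costs[0, 0] == pytest.approx(4.0)

    def test_matches_per_pair_distances(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
        transform = RigidTransform(rng.normal(size=3), rng.uniform(-np.pi, np.pi, 3))
        costs = build_cost_matrix(transform, a, b)
        moved = apply_transform(transform, a)
        for i in range(5):
            for j in range(7):
                assert costs[i, j] == pytest.approx(
                    np.sum((moved[i] - b[j]) ** 2), abs=1e-10
                )


class TestSolveKlap:
    def test_zero_diagonal_full_cardinality(self):
        costs = np.full((3, 3), 10.0)
        np.fill_diagonal(costs, 0.0)
        res = solve_klap(costs, 3)
        assert res.objective == 0.0
        assert res.rmsd == 0.0
        assert res.alignment.sorted_by_a() == ((1, 1), (2, 2), (3, 3))

    def test_k_one_picks_global_minimum_entry(self):
        rng = np.random.default_rng(2)
        costs = rng.random((5, 6))
        res = solve_klap(costs, 1)
        assert res.objective == pytest.approx(costs.min())

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            solve_klap(np.ones((3, 4)), 0)
        with pytest.raises(ValueError):
            solve_klap(np.ones((3, 4)), 4)

    def test_exact_cardinality_and_one_to_one(self):
        rng = np.random.default_rng(3)
        costs = rng.random((6, 8))
        for k in (1, 3, 6):
            res = solve_klap(costs, k)
            assert res.alignment.k == k  # one-to-one enforced by Alignment itself

    def test_rmsd_objective_consistency(self):
        rng = np.random.default_rng(4)
        costs = rng.random((5, 5)) * 7
        res = solve_klap(costs, 4)
        assert res.rmsd == pytest.approx(np.sqrt(res.objective / 4), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_enumeration(self, klap_bruteforce, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 8, size=2)
        costs = rng.random((m, n)) * 10
        for k in range(1, min(m, n) + 1):
            res = solve_klap(costs, k)
            assert res.objective == pytest.approx(klap_bruteforce(costs, k), abs=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_objective_nondecreasing_in_k(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 9, size=2)
        costs = rng.random((m, n)) * 5
        objectives = [solve_klap(costs, k).objective for k in range(1, min(m, n) + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(objectives, objectives[1:]))


class TestEvaluateF:
    def test_self_alignment_zero(self):
        pts = np.random.default_rng(5).normal(size=(8, 3)) * 4
        res = evaluate_F(RigidTransform.identity(), pts, pts, 8)
        assert res.rmsd < 1e-12

    def test_uniform_translation_exact_rmsd(self):
        pts = np.random.default_rng(6).normal(size=(6, 3)) * 4
        shifted = pts + [5.0, 0, 0]
        res = evaluate_F(RigidTransform.identity(), pts, shifted, 6)
        # every candidate pairing is displaced by the same vector, so the
        # optimum is the identity pairing at exactly 5 A
        assert res.rmsd == pytest.approx(5.0, abs=1e-9)

    def test_lower_bounds_any_feasible_pairing(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(7, 3)) * 3, rng.normal(size=(7, 3)) * 3
        res = evaluate_F(RigidTransform.identity(), a, b, 5)
        for trial in range(20):
            perm = rng.permutation(7)[:5]
            rows = rng.permutation(7)[:5]
            pairs = [(int(r) + 1, int(c) + 1) for r, c in zip(rows, perm)]
            assert res.rmsd <= rmsd_of_assignment(a, b, pairs) + 1e-12
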