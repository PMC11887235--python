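"""Information-theoretic primitives and the draw-and-merge optimizer.

The central contract: the incremental merger cost used inside the sweep
must equal the difference of the objective L = I(T;Y) - I(T;X)/lambda
recomputed from scratch on the partitions before and after the merge.
"""

import itertools

import numpy as np
import pytest

from logstage.phantom import generate_feature_blobs
from logstage.sib import (DRAWN, ClusterState, SibConfig, features_to_joint,
                          js_divergence, kmeans_baseline, merger_cost,
                          mutual_information, nmi, objective_from_scratch,
                          sib_cluster)


def _state_without(joint, assignment, k, x):
    """Build a ClusterState with point x drawn out, stats from scratch."""
    a = assignment.copy()
    a[x] = DRAWN
    sums = np.stack([joint.p_xy[a == t].sum(axis=0) for t in range(k)])
    p_t = sums.sum(axis=1)
    with np.errstate(invalid="ignore"):
        cond = np.where(p_t[:, None] > 0, sums / np.where(p_t[:, None] > 0, p_t[:, None], 1.0), 0.0)
    return a, ClusterState(assignment=a, p_t=p_t, p_y_given_t=cond, objective=0.0, k=k)


class TestMutualInformation:
    def test_product_joint_is_zero(self, rng):
        p = rng.dirichlet(np.ones(5))
        q = rng.dirichlet(np.ones(7))
        assert mutual_information(np.outer(p, q)) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_half_half_is_ln2(self):
        assert mutual_information(np.diag([0.5, 0.5])) == pytest.approx(np.log(2), abs=1e-12)

    def test_uniform_2x2_is_zero(self):
        assert mutual_information(np.full((2, 2), 0.25)) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_joints(self, rng):
        for _ in range(20):
            j = rng.dirichlet(np.ones(12)).reshape(3, 4)
            assert mutual_information(j) >= -1e-12

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.full((2, 2), 0.4))


class TestJSDivergence:
    def test_identical_distributions_zero(self, rng):
        p = rng.dirichlet(np.ones(6))
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_equal_weights_ln2(self):
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(np.log(2), abs=1e-12)

    def test_disjoint_asymmetric_weights_binary_entropy(self):
        # disjoint supports attain the upper bound H(w)
        h = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert js_divergence([1, 0], [0, 1], (0.9, 0.1)) == pytest.approx(h, abs=1e-12)

    def test_bounds_on_random_pairs(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            w1 = rng.uniform(0.05, 0.95)
            js = js_divergence(p, q, (w1, 1 - w1))
            h = -(w1 * np.log(w1) + (1 - w1) * np.log(1 - w1))
            assert -1e-12 <= js <= h + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            js_divergence([1, 0], [0.5, 0.25, 0.25])


class TestFeaturesToJoint:
    def test_indicator_rows(self):
        j = features_to_joint(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(j.p_xy, [[0.5, 0.0], [0.0, 0.5]], atol=1e-6)

    def test_mass_and_nonnegativity(self, rng):
        j = features_to_joint(rng.uniform(0, 5, (7, 4)))
        assert j.p_xy.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(j.p_xy >= 0)
        assert np.allclose(j.p_y_given_x.sum(axis=1), 1.0)

    def test_negative_entries_clipped(self):
        j = features_to_joint(np.array([[-5.0, 1.0], [1.0, 1.0]]))
        assert j.p_xy[0, 0] < 1e-7  # only the epsilon floor remains

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            features_to_joint(np.array([[np.inf, 1.0], [0.0, 1.0]]))


class TestMergerCostOracle:
    def test_incremental_equals_from_scratch(self, rng):
        """100 random instances: merger cost == L(drawn) - L(merged) to 1e-9."""
        lam = 100.0
        for trial in range(100):
            n, d = 6 + int(rng.integers(0, 5)), 4
            k = 2 + int(rng.integers(0, 2))
            F = rng.uniform(0, 1, (n, d))
            joint = features_to_joint(F)
            assignment = rng.integers(0, k, n)
            x = int(rng.integers(0, n))
            drawn_assign, state = _state_without(joint, assignment, k, x)
            L_drawn = objective_from_scratch(joint, drawn_assign, k, lam)
            for t in range(k):
                merged = drawn_assign.copy()
                merged[x] = t
                L_after = objective_from_scratch(joint, merged, k, lam)
                inc = merger_cost(state, joint, x, t, lam)
                assert inc == pytest.approx(L_drawn - L_after, abs=1e-9)

    def test_identical_conditionals_zero_information_cost(self):
        # merging a point into a cluster with the same p(y|.) loses no I(T;Y);
        # only the compression term moves, so cost = -dI1/lam < 0
        F = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 1.0], [1.0, 3.0]])
        joint = features_to_joint(F)
        assignment = np.array([0, 0, 1, 1])
        drawn_assign, state = _state_without(joint, assignment, 2, 0)
        cost = merger_cost(state, joint, 0, 0, 100.0)
        assert cost <= 0.0
        L_drawn = objective_from_scratch(joint, drawn_assign, 2, 100.0)
        merged = drawn_assign.copy()
        merged[0] = 0
        assert cost == pytest.approx(
            L_drawn - objective_from_scratch(joint, merged, 2, 100.0), abs=1e-12)

    def test_merge_into_empty_cluster_is_free(self):
        joint = features_to_joint(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))
        a = np.array([0, 0, DRAWN])
        sums = np.stack([joint.p_xy[a == t].sum(axis=0) for t in range(2)])
        p_t = sums.sum(axis=1)
        cond = np.where(p_t[:, None] > 0, sums / np.maximum(p_t[:, None], 1e-300), 0.0)
        state = ClusterState(assignment=a, p_t=p_t, p_y_given_t=cond, objective=0.0, k=2)
        assert merger_cost(state, joint, 2, 1, 100.0) == 0.0

    def test_undrawn_point_rejected(self):
        joint = features_to_joint(np.eye(3))
        a = np.array([0, 1, 0])
        state = ClusterState(assignment=a, p_t=np.array([2 / 3, 1 / 3]),
                             p_y_given_t=np.ones((2, 3)) / 3, objective=0.0, k=2)
        with pytest.raises(ValueError):
            merger_cost(state, joint, 0, 1, 100.0)


class TestSibCluster:
    def test_duplicated_groups_recovered_exactly(self):
        a = np.array([3.0, 1.0, 0.2])
        b = np.array([0.1, 2.0, 4.0])
        F = np.stack([a] * 5 + [b] * 5)
        state = sib_cluster(F, SibConfig(k=2, seed=0, restarts=3))
        truth = np.array([0] * 5 + [1] * 5)
        assert nmi(state.assignment, truth) == pytest.approx(1.0)

    def test_beats_brute_force_partitions(self, rng):
        """Returned objective >= 95% of all partitions, small instances."""
        lam = 100.0
        wins = []
        for trial in range(20):
            n, k = 8, 2
            F = rng.uniform(0, 1, (n, 4))
            joint = features_to_joint(F)
            state = sib_cluster(F, SibConfig(k=k, lam=lam, seed=trial, restarts=3))
            objs = []
            for bits in itertools.product(range(k), repeat=n):
                a = np.array(bits)
                if len(np.unique(a)) < k:
                    continue
                objs.append(objective_from_scratch(joint, a, k, lam))
            frac = np.mean(np.array(objs) <= state.objective + 1e-12)
            wins.append(frac)
        assert np.mean(np.array(wins) >= 0.95) == 1.0

    def test_objective_trace_monotone_nondecreasing(self, rng):
        F = rng.uniform(0, 1, (60, 6))
        state = sib_cluster(F, SibConfig(k=4, seed=3, restarts=2))
        diffs = np.diff(np.array(state.objective_trace))
        assert np.all(diffs >= -1e-12)

    def test_convergence_within_pass_budget(self, rng):
        F, _ = generate_feature_blobs(300, 8, 4, 5.0, seed=5)
        state = sib_cluster(F, SibConfig(seed=2, restarts=2, max_passes=50))
        assert state.converged and state.passes <= 50

    def test_data_processing_inequality(self, rng):
        F = rng.uniform(0, 2, (40, 5))
        joint = features_to_joint(F)
        i_xy = mutual_information(joint.p_xy)
        state = sib_cluster(F, SibConfig(seed=1, restarts=2))
        p_ty = np.stack([joint.p_xy[state.assignment == t].sum(axis=0) for t in range(4)])
        assert mutual_information(p_ty) <= i_xy + 1e-9

    def test_n_equals_k_preserves_all_information(self):
        F = np.eye(4) + 0.01
        joint = features_to_joint(F)
        state = sib_cluster(F, SibConfig(k=4, seed=0, restarts=1))
        assert len(np.unique(state.assignment)) == 4
        p_ty = np.stack([joint.p_xy[state.assignment == t].sum(axis=0) for t in range(4)])
        assert mutual_information(p_ty) == pytest.approx(
            mutual_information(joint.p_xy), abs=1e-12)

    def test_blob_recovery_across_seeds(self):
        """Well-separated Gaussian blobs are recovered with NMI >= 0.9."""
        for seed in range(5):
            F, labels = generate_feature_blobs(200, 16, 4, 10.0, seed=7 + seed)
            state = sib_cluster(F, SibConfig(seed=seed))
            assert nmi(state.assignment, labels) >= 0.9

    def test_null_separation_stays_low(self):
        F, labels = generate_feature_blobs(500, 16, 4, 0.0, seed=3)
        state = sib_cluster(F, SibConfig(seed=1, restarts=2))
        assert nmi(state.assignment, labels) < 0.15

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sib_cluster(np.ones((3, 4)), SibConfig(k=4))

    def test_pass_cost_scales_linearly_in_n_and_k(self):
        """One sweep evaluates at most N*k merger costs (O(k N D) per pass)."""
        for n, k in [(50, 2), (100, 4), (200, 4)]:
            F, _ = generate_feature_blobs(n, 8, k, 5.0, seed=1)
            state = sib_cluster(F, SibConfig(k=k, seed=0, restarts=1))
            assert state.cost_evals <= state.passes * n * k


class TestNmi:
    def test_identical_labelings(self):
        assert nmi([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_permutation_invariance(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        assert nmi(a, (a + 1) % 3) == pytest.approx(1.0)

    def test_independent_labelings_near_zero(self, rng):
        a = rng.integers(0, 4, 2000)
        b = rng.integers(0, 4, 2000)
        assert nmi(a, b) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi([0, 1], [0, 1, 2])


def test_kmeans_baseline_recovers_blobs():
    F, labels = generate_feature_blobs(200, 16, 4, 10.0, seed=7)
    assert nmi(kmeans_baseline(F, 4, seed=0), labels) >= 0.9
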