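import numpy as np
import pytest

from ibfcc import (
    DataMatrix,
    FitConfig,
    IBDistanceTensor,
    compute_centroids,
    compute_ib_distances,
    defuzzify,
    fit,
    ib_merge_cost,
    init_memberships,
    normalize_rows,
    objective,
    objective_lower_bound,
    update_feature_memberships,
    update_object_memberships,
)
from ibfcc.core import InvalidConfigError


def random_distribution(rng, k):
    v = rng.uniform(0.05, 1.0, size=k)
    return v / v.sum()


class TestInitMemberships:
    def test_seeded_determinism(self):
        a = init_memberships(3, 5, 4, seed=7)
        b = init_memberships(3, 5, 4, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_constraints(self):
        U, V = init_memberships(4, 9, 6, seed=3)
        np.testing.assert_allclose(U.sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(V.sum(axis=1), 1.0, atol=1e-12)

    def test_entries_strictly_interior(self):
        U, V = init_memberships(2, 2, 2, seed=0)
        for m in (U, V):
            assert np.all(m > 0) and np.all(m < 1)

    def test_more_clusters_than_objects_rejected(self):
        with pytest.raises(InvalidConfigError):
            init_memberships(5, 3, 4, seed=0)


class TestCentroids:
    def test_uniform_memberships_give_column_means(self, small_random_data):
        C, N = 3, small_random_data.n_objects
        U = np.full((C, N), 1.0 / C)
        P = compute_centroids(U, small_random_data)
        expected = small_random_data.values.mean(axis=0)
        for c in range(C):
            np.testing.assert_allclose(P[c], expected, atol=1e-12)

    def test_hard_memberships_give_plain_means(self):
        data = DataMatrix(values=np.array([[9.0], [1.0], [3.0]]))
        U = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.0]])
        P = compute_centroids(U, data)
        assert P[0, 0] == pytest.approx(2.0)
        assert P[1, 0] == pytest.approx(9.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(11)
        data = DataMatrix(values=rng.uniform(0, 1, size=(6, 4)))
        U = rng.uniform(0.1, 1, size=(3, 6))
        U /= U.sum(axis=0)
        P = compute_centroids(U, data)
        for c in range(3):
            for j in range(4):
                expected = sum(
                    U[c, i] * data.values[i, j] for i in range(6)
                ) / sum(U[c, i] for i in range(6))
                assert P[c, j] == pytest.approx(expected, abs=1e-12)

    def test_normalized_rows_give_normalized_centroids(self, small_random_data):
        data = normalize_rows(small_random_data)
        U, _ = init_memberships(3, data.n_objects, data.n_features, seed=1)
        P = compute_centroids(U, data)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestDefuzzify:
    def test_argmax_assignment(self):
        U = np.array([[0.2], [0.7], [0.1]])
        assignments, sizes = defuzzify(U)
        assert assignments[0] == 1
        assert list(sizes) == [0, 1, 0]

    def test_ties_break_to_lowest_index(self):
        U = np.array([[0.5], [0.5]])
        assignments, _ = defuzzify(U)
        assert assignments[0] == 0

    def test_uniform_memberships_collapse_to_first_cluster(self):
        U = np.full((4, 12), 0.25)
        assignments, sizes = defuzzify(U)
        assert np.all(assignments == 0)
        assert list(sizes) == [12, 0, 0, 0]
        assert sizes.sum() == 12


class TestIBDistances:
    def test_row_equal_to_centroid_has_zero_distance(self):
        row = np.array([0.3, 0.5, 0.2])
        data = DataMatrix(values=np.vstack([row, [0.6, 0.2, 0.2]]))
        P = np.vstack([row, [0.1, 0.1, 0.8]])
        dist = compute_ib_distances(data, P, sizes=np.array([4, 1]))
        np.testing.assert_allclose(dist.d[0, 0], 0.0, atol=1e-15)

    def test_empty_cluster_treated_as_singleton(self):
        rng = np.random.default_rng(5)
        data = DataMatrix(values=rng.dirichlet(np.ones(4), size=3))
        P = rng.dirichlet(np.ones(4), size=2)
        d_empty = compute_ib_distances(data, P, sizes=np.array([0, 2])).d
        d_one = compute_ib_distances(data, P, sizes=np.array([1, 2])).d
        np.testing.assert_allclose(d_empty, d_one)
        assert np.any(d_empty[0] > 0)  # not a universal attractor

    def test_blend_lies_between_row_and_centroid(self):
        rng = np.random.default_rng(8)
        data = DataMatrix(values=rng.dirichlet(np.ones(5), size=4))
        P = rng.dirichlet(np.ones(5), size=3)
        dist = compute_ib_distances(data, P, sizes=np.array([2, 1, 1]))
        x = data.values[None, :, :]
        p = P[:, None, :]
        lo = np.minimum(np.broadcast_to(x, dist.t.shape), np.broadcast_to(p, dist.t.shape))
        hi = np.maximum(np.broadcast_to(x, dist.t.shape), np.broadcast_to(p, dist.t.shape))
        assert np.all(dist.t >= lo - 1e-15) and np.all(dist.t <= hi + 1e-15)

    def test_matches_mutual_information_loss_oracle(self):
        """Summing d_cij over features equals the two-cluster merge cost
        computed on the explicit joint distribution with priors 1/N, |c|/N."""
        rng = np.random.default_rng(100)
        N = 4
        for _ in range(200):
            K = rng.integers(2, 9)
            x = random_distribution(rng, K)
            p = random_distribution(rng, K)
            size_c = int(rng.integers(1, N))
            data = DataMatrix(values=np.vstack([x] * N))  # only row 0 matters
            dist = compute_ib_distances(data, p[None, :], sizes=np.array([size_c]))
            direct = ib_merge_cost(1.0 / N, x, size_c / N, p)
            assert dist.d[0, 0].sum() == pytest.approx(direct, abs=1e-10)

    def test_negative_inputs_rejected(self):
        data = DataMatrix(values=np.ones((2, 2)))
        with pytest.raises(ValueError, match="nonnegative"):
            compute_ib_distances(data, np.array([[-0.1, 1.1]]), np.array([1]))


class TestMergeCost:
    def test_identical_distributions_lose_nothing(self):
        d = np.array([0.25, 0.75])
        assert ib_merge_cost(0.3, d, 0.7, d) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_distributions_give_log_two(self):
        cost = ib_merge_cost(0.5, np.array([1.0, 0.0]), 0.5, np.array([0.0, 1.0]))
        assert cost == pytest.approx(np.log(2.0), abs=1e-12)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            k = rng.integers(2, 6)
            cost = ib_merge_cost(
                rng.uniform(0.05, 1),
                random_distribution(rng, k),
                rng.uniform(0.05, 1),
                random_distribution(rng, k),
            )
            assert cost >= -1e-15

    def test_unnormalized_distribution_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ib_merge_cost(0.5, np.array([0.5, 0.4]), 0.5, np.array([0.5, 0.5]))


def _tensor(d):
    return IBDistanceTensor(d=d, t=np.zeros_like(d))


class TestMembershipUpdates:
    def test_constant_distances_give_uniform_feature_memberships(self):
        C, N, K = 2, 3, 5
        d = np.full((C, N, K), 0.37)
        U = np.full((C, N), 0.5)
        V = update_feature_memberships(U, _tensor(d), T_v=1.0)
        np.testing.assert_allclose(V, 1.0 / K, atol=1e-12)

    def test_feature_update_direct_value(self):
        # one cluster with exponent sums (0, ln 2) -> memberships (2/3, 1/3)
        d = np.array([[[0.0, np.log(2.0)]]])  # C=1, N=1, K=2
        U = np.array([[1.0]])
        V = update_feature_memberships(U, _tensor(d), T_v=1.0)
        np.testing.assert_allclose(V[0], [2.0 / 3.0, 1.0 / 3.0], atol=1e-12)

    def test_large_T_v_gives_uniform(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 1, size=(3, 4, 6))
        U = np.full((3, 4), 1 / 3)
        V = update_feature_memberships(U, _tensor(d), T_v=1e9)
        assert np.abs(V - 1.0 / 6.0).max() < 1e-6

    def test_object_update_direct_value(self):
        # aggregated distances (0, ln 3) at T_u=1 -> column (3/4, 1/4)
        d = np.stack([np.zeros((1, 1)), np.full((1, 1), np.log(3.0))])  # C=2,N=1,K=1
        V = np.ones((2, 1))
        U = update_object_memberships(V, _tensor(d), T_u=1.0)
        np.testing.assert_allclose(U[:, 0], [0.75, 0.25], atol=1e-12)

    def test_equal_aggregated_distances_give_uniform_objects(self):
        d = np.full((4, 3, 2), 1.23)
        V = np.full((4, 2), 0.5)
        U = update_object_memberships(V, _tensor(d), T_u=0.7)
        np.testing.assert_allclose(U, 0.25, atol=1e-12)

    def test_small_T_u_gives_hard_argmin(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.1, 1, size=(3, 5, 4))
        V = np.full((3, 4), 0.25)
        U = update_object_memberships(V, _tensor(d), T_u=1e-9)
        agg = np.einsum("cj,cij->ci", V, d)
        hard = np.zeros_like(U)
        hard[np.argmin(agg, axis=0), np.arange(5)] = 1.0
        assert np.abs(U - hard).max() < 1e-6

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 1, size=(3, 4, 5))
        V = np.full((3, 5), 0.2)
        U1 = update_object_memberships(V, _tensor(d), T_u=0.5)
        U2 = update_object_memberships(V, _tensor(d + 123.0), T_u=0.5)
        np.testing.assert_allclose(U1, U2, atol=1e-9)

    def test_constraints_after_updates(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(0, 2, size=(5, 8, 7))
        U, V = init_memberships(5, 8, 7, seed=1)
        V2 = update_feature_memberships(U, _tensor(d), T_v=0.3)
        U2 = update_object_memberships(V2, _tensor(d), T_u=0.3)
        np.testing.assert_allclose(V2.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(U2.sum(axis=0), 1.0, atol=1e-10)

    def test_nonfinite_distances_rejected(self):
        d = np.full((2, 2, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            update_feature_memberships(np.full((2, 2), 0.5), _tensor(d), 1.0)


class TestObjective:
    def test_uniform_memberships_zero_distance_hit_the_bound(self):
        C, N, K = 3, 5, 4
        U = np.full((C, N), 1.0 / C)
        V = np.full((C, K), 1.0 / K)
        d = np.zeros((C, N, K))
        cfg = FitConfig(C=C, T_u=0.7, T_v=1.3)
        J = objective(U, V, _tensor(d), cfg.T_u, cfg.T_v)
        assert J == pytest.approx(objective_lower_bound(cfg, N, K), abs=1e-12)

    def test_one_hot_memberships_zero_distance_give_zero(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        d = np.zeros((2, 2, 2))
        assert objective(U, V, _tensor(d), 1.0, 1.0) == 0.0

    def test_matches_triple_sum(self):
        rng = np.random.default_rng(5)
        C, N, K = 2, 3, 2
        U, V = init_memberships(C, N, K, seed=5)
        d = rng.uniform(0, 1, size=(C, N, K))
        expected = sum(
            U[c, i] * V[c, j] * d[c, i, j]
            for c in range(C)
            for i in range(N)
            for j in range(K)
        )
        expected += 1.1 * sum(u * np.log(u) for u in U.ravel())
        expected += 0.9 * sum(v * np.log(v) for v in V.ravel())
        J = objective(U, V, _tensor(d), 1.1, 0.9)
        assert J == pytest.approx(expected, abs=1e-12)

    def test_lower_bound_arithmetic(self):
        cfg = FitConfig(C=2, T_u=1.0, T_v=1.0)
        M = objective_lower_bound(cfg, N=10, K=5)
        assert M == pytest.approx(10 * np.log(0.5) + 2 * np.log(0.2), abs=1e-10)

    def test_lower_bound_vanishes_for_single_feature(self):
        cfg = FitConfig(C=3, T_u=1.0, T_v=5.0)
        assert objective_lower_bound(cfg, N=4, K=1) == pytest.approx(
            4 * np.log(1 / 3), abs=1e-12
        )


class TestFit:
    def test_huge_tolerance_converges_immediately(self, small_random_data):
        res = fit(small_random_data, FitConfig(C=2, xi=2.0, seed=0))
        assert res.converged and res.iterations == 1

    def test_trace_respects_lower_bound(self, small_random_data):
        cfg = FitConfig(C=3, T_u=0.01, T_v=0.05, seed=2, tau_max=40)
        res = fit(small_random_data, cfg)
        M = objective_lower_bound(cfg, small_random_data.n_objects, small_random_data.n_features)
        assert all(J >= M - 1e-12 for J in res.objective_trace)

    def test_model_invariants(self, small_random_data):
        res = fit(small_random_data, FitConfig(C=2, T_u=0.01, T_v=0.05, seed=3))
        m = res.model
        np.testing.assert_allclose(m.U.sum(axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(m.V.sum(axis=1), 1.0, atol=1e-10)
        assert m.sizes.sum() == small_random_data.n_objects
        assert res.iterations <= res.config.tau_max
        assert res.max_constraint_violation < 1e-10

    def test_seeded_determinism(self, small_random_data):
        r1 = fit(small_random_data, FitConfig(C=2, seed=9))
        r2 = fit(small_random_data, FitConfig(C=2, seed=9))
        assert np.array_equal(r1.model.U, r2.model.U)
        assert r1.objective_trace == r2.objective_trace

    def test_invalid_cluster_count_rejected(self, small_random_data):
        with pytest.raises(InvalidConfigError):
            fit(small_random_data, FitConfig(C=1))
        with pytest.raises(InvalidConfigError):
            fit(small_random_data, FitConfig(C=99))

    def test_recovers_planted_blocks(self, standard_block_data):
        """End-to-end: median F over 10 restarts >= 0.9 on the standard fixture."""
        from ibfcc import defuzzify, evaluate
        from ibfcc.tuning import suggest_temperatures

        data, _ = standard_block_data
        T_u, T_v = suggest_temperatures(data, 3)
        fs = []
        for seed in range(10):
            res = fit(data, FitConfig(C=3, T_u=T_u, T_v=T_v, seed=seed))
            rep = evaluate(defuzzify(res.model.U)[0], data.labels, C=3)
            fs.append(rep.f_measure)
        assert np.median(fs) >= 0.9


class TestCoordinateDescent:
    """The closed-form updates minimize the objective over their own block."""

    def _instance(self):
        rng = np.random.default_rng(21)
        C, N, K = 2, 3, 2
        d = rng.uniform(0, 1, size=(C, N, K))
        U, V = init_memberships(C, N, K, seed=21)
        return d, U, V

    def test_u_update_beats_random_feasible_memberships(self):
        d, _, V = self._instance()
        T_u = T_v = 0.2
        U_star = update_object_memberships(V, _tensor(d), T_u)
        J_star = objective(U_star, V, _tensor(d), T_u, T_v)
        rng = np.random.default_rng(99)
        for _ in range(500):
            U_rand = rng.uniform(0.01, 1, size=U_star.shape)
            U_rand /= U_rand.sum(axis=0)
            assert J_star <= objective(U_rand, V, _tensor(d), T_u, T_v) + 1e-12

    def test_v_update_beats_random_feasible_memberships(self):
        d, U, _ = self._instance()
        T_u = T_v = 0.2
        V_star = update_feature_memberships(U, _tensor(d), T_v)
        J_star = objective(U, V_star, _tensor(d), T_u, T_v)
        rng = np.random.default_rng(98)
        for _ in range(500):
            V_rand = rng.uniform(0.01, 1, size=V_star.shape)
            V_rand /= V_rand.sum(axis=1, keepdims=True)
            assert J_star <= objective(U, V_rand, _tensor(d), T_u, T_v) + 1e-12
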