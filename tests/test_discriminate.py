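import numpy as np
import pytest

from beetlemorph.discriminate import (
    cva,
    distance_matrix_layout,
    mahalanobis_distance,
    pairwise_group_tests,
    permutation_test,
    pooled_within_covariance,
)
from beetlemorph.errors import ParameterError
from beetlemorph.procrustes import gpa

from conftest import random_configuration


def two_gaussian_groups(rng, n_per, d, delta, cov_chol=None):
    A = rng.normal(size=(n_per, d))
    B = rng.normal(size=(n_per, d))
    if cov_chol is not None:
        A = A @ cov_chol.T
        B = B @ cov_chol.T
    B = B + delta
    X = np.vstack([A, B])
    labels = np.array(["a"] * n_per + ["b"] * n_per)
    return X, labels


class TestPooledCovariance:
    def test_identical_scatter_recovered(self, rng):
        # both groups share centered scatter S: pooled = S (up to divisor)
        C = rng.normal(size=(10, 4))
        C -= C.mean(axis=0)
        X = np.vstack([C, C + 5.0])
        labels = ["a"] * 10 + ["b"] * 10
        pooled = pooled_within_covariance(X, labels)
        np.testing.assert_allclose(pooled.matrix, 2 * C.T @ C / (20 - 2), atol=1e-12)

    def test_sampling_consistency(self, rng):
        L = np.linalg.cholesky(np.array([[2.0, 0.6], [0.6, 1.0]]))
        X, labels = two_gaussian_groups(rng, 1000, 2, delta=3.0, cov_chol=L)
        pooled = pooled_within_covariance(X, labels)
        np.testing.assert_allclose(pooled.matrix, L @ L.T, rtol=0.08)

    def test_shape_data_rank_deficiency(self, rng):
        configs = np.stack([random_configuration(rng, k=10) for _ in range(40)])
        aligned = gpa(configs)
        labels = ["a"] * 20 + ["b"] * 20
        pooled = pooled_within_covariance(aligned.tangent, labels)
        # translation (x2), rotation and scaling each remove one dof
        assert pooled.rank <= 2 * 10 - 4
        full = np.linalg.eigvalsh(pooled.matrix)
        assert (full < 1e-10 * full.max()).sum() >= 4

    def test_singleton_group_error(self, rng):
        with pytest.raises(ParameterError, match="lonely"):
            pooled_within_covariance(
                rng.normal(size=(4, 3)), ["a", "a", "a", "lonely"]
            )


class TestMahalanobis:
    def test_zero_and_euclidean_reduction(self, rng):
        X, labels = two_gaussian_groups(rng, 200, 5, delta=0.0)
        pooled = pooled_within_covariance(X, labels)
        mu = X[:200].mean(axis=0)
        assert mahalanobis_distance(mu, mu, pooled) == 0.0
        # identity covariance: D equals the Euclidean distance
        eye = pooled_within_covariance(
            np.vstack([np.eye(5), -np.eye(5), np.zeros((2, 5))]) * 1.0,
            ["a"] * 5 + ["b"] * 5 + ["a", "b"],
        )
        # construct an exactly identity pooled covariance instead
        from beetlemorph.discriminate import PooledCovariance

        ident = PooledCovariance(
            matrix=np.eye(5),
            eigenvalues=np.ones(5),
            retained_basis=np.eye(5),
            rank=5,
            n=10,
            n_groups=2,
        )
        d = np.zeros(5)
        d[0] = 3.0
        assert mahalanobis_distance(d, np.zeros(5), ident) == pytest.approx(3.0)

    def test_closed_form_recovery(self, rng):
        d = 8
        A = rng.normal(size=(d, d))
        Sigma = A @ A.T / d + np.eye(d)
        L = np.linalg.cholesky(Sigma)
        delta = rng.normal(size=d)
        X, labels = two_gaussian_groups(rng, 2000, d, delta=delta, cov_chol=L)
        pooled = pooled_within_covariance(X, labels)
        mu_a = X[:2000].mean(axis=0)
        mu_b = X[2000:].mean(axis=0)
        D = mahalanobis_distance(mu_a, mu_b, pooled)
        expected = np.sqrt(delta @ np.linalg.solve(Sigma, delta))
        assert D == pytest.approx(expected, rel=0.05)

    def test_invariance_under_linear_transform(self, rng):
        X, labels = two_gaussian_groups(rng, 100, 4, delta=1.0)
        pooled = pooled_within_covariance(X, labels)
        D1 = mahalanobis_distance(X[:100].mean(0), X[100:].mean(0), pooled)
        M = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        Y = X @ M.T
        pooled2 = pooled_within_covariance(Y, labels)
        D2 = mahalanobis_distance(Y[:100].mean(0), Y[100:].mean(0), pooled2)
        assert D2 == pytest.approx(D1, rel=1e-6)


class TestCva:
    def test_two_group_separation_equals_D2(self, rng):
        X, labels = two_gaussian_groups(rng, 60, 6, delta=2.0)
        res = cva(X, labels)
        assert res.scores.shape[1] == 1
        pooled = pooled_within_covariance(X, labels)
        D = mahalanobis_distance(X[:60].mean(0), X[60:].mean(0), pooled)
        sep = abs(res.group_means["a"][0] - res.group_means["b"][0])
        assert sep**2 == pytest.approx(D**2, rel=1e-6)

    def test_axis_count_and_whitening(self, rng):
        X = rng.normal(size=(90, 7))
        labels = np.repeat(["a", "b", "c"], 30)
        res = cva(X, labels)
        assert res.scores.shape[1] == 2  # min(g-1, rank)
        # pooled within-group covariance of canonical scores is identity
        W = np.zeros((2, 2))
        for g in "abc":
            S = res.scores[labels == g]
            C = S - S.mean(axis=0)
            W += C.T @ C
        W /= 90 - 3
        np.testing.assert_allclose(W, np.eye(2), atol=1e-8)

    def test_identical_means_give_null_eigenvalues(self, rng):
        X = rng.normal(size=(600, 5))
        labels = np.repeat(["a", "b", "c"], 200)
        null = cva(X, labels)
        shifted = X + np.repeat([0.0, 5.0, 10.0], 200)[:, None]
        separated = cva(shifted, labels)
        # null eigenvalues are pure sampling noise, far below a planted signal
        assert null.eigenvalues.max() < 0.01 * separated.eigenvalues.max()

    def test_collinear_group_means(self, rng):
        d = 5
        X = np.vstack(
            [
                rng.normal(size=(50, d)) * 0.05 + 0.0,
                rng.normal(size=(50, d)) * 0.05 + 1.0,
                rng.normal(size=(50, d)) * 0.05 + 2.0,
            ]
        )
        labels = np.repeat(["a", "b", "c"], 50)
        res = cva(X, labels)
        assert res.eigenvalues[0] / res.eigenvalues.sum() > 0.99


class TestPermutationTest:
    def test_constant_statistic_p_is_one(self, rng):
        res = permutation_test(
            lambda data, labels: 1.0, rng.normal(size=(20, 2)),
            ["a"] * 10 + ["b"] * 10, rounds=99, seed=1,
        )
        assert res.p_value == 1.0

    def test_extreme_observation_floor(self, rng):
        # a planted separation so large that the observed statistic beats
        # every permuted one: p attains its floor 1/(rounds + 1)
        X = np.vstack([rng.normal(size=(12, 2)), rng.normal(size=(12, 2)) + 100.0])
        labels = np.array(["a"] * 12 + ["b"] * 12)

        def stat(data, labs):
            labs = np.asarray(labs)
            return np.linalg.norm(
                data[labs == "a"].mean(0) - data[labs == "b"].mean(0)
            )

        res = permutation_test(stat, X, labels, rounds=1000, seed=2)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_rounds_validation(self):
        with pytest.raises(ParameterError):
            permutation_test(lambda d, l: 0.0, None, ["a", "b"], rounds=0)

    def test_reproducible_given_seed(self, rng):
        X = rng.normal(size=(30, 3))
        labels = ["a"] * 15 + ["b"] * 15

        def stat(data, labs):
            labs = np.asarray(labs)
            return np.linalg.norm(
                data[labs == "a"].mean(0) - data[labs == "b"].mean(0)
            )

        r1 = permutation_test(stat, X, labels, rounds=200, seed=42)
        r2 = permutation_test(stat, X, labels, rounds=200, seed=42)
        assert r1.p_value == r2.p_value
        r3 = permutation_test(stat, X, labels, rounds=200, seed=43)
        assert r1.p_value != r3.p_value or r1.null_mean != r3.null_mean


class TestPairwise:
    def test_strong_separation_rejected_both_metrics(self, rng):
        X, labels = two_gaussian_groups(rng, 30, 6, delta=5.0 / np.sqrt(6))
        # planted separation 5x the within-group SD overall
        pairs = pairwise_group_tests(X, labels, rounds=199, seed=9)
        row = pairs.iloc[0]
        assert row["p_mahalanobis"] < 0.05
        assert row["p_procrustes"] < 0.05

    def test_matrix_layout(self, rng):
        X = rng.normal(size=(60, 4))
        labels = np.repeat(["a", "b", "c"], 20)
        pairs = pairwise_group_tests(X, labels, rounds=49, seed=9)
        M = distance_matrix_layout(pairs, "mahalanobis")
        assert M.loc["b", "a"] == pairs.set_index(["group_a", "group_b"]).loc[
            ("a", "b"), "mahalanobis_d"
        ]
        assert 0 < M.loc["a", "b"] <= 1  # p-value above the diagonal
        assert np.isnan(M.loc["a", "a"])

    def test_null_pvalues_roughly_uniform(self, rng):
        # under exchangeable labels, p-values are (super-)uniform
        ps = []
        for s in range(120):
            r = np.random.default_rng(s)
            X = r.normal(size=(24, 4))
            labels = ["a"] * 12 + ["b"] * 12
            pairs = pairwise_group_tests(X, labels, rounds=99, seed=s)
            ps.append(pairs.iloc[0]["p_procrustes"])
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.1
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01
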