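"""Stage 1: known-factor removal, surrogate extraction, adjustment."""

import numpy as np
import pytest
import scipy.linalg

import sosa
from sosa.adjust import _pearson_with_vector


def make_groups(sizes):
    n = sum(sizes)
    G = np.zeros((n, len(sizes)))
    start = 0
    for j, s in enumerate(sizes):
        G[start:start + s, j] = 1.0
        start += s
    return G


class TestExpressionMatrixAndDesign:
    def test_rejects_missing_and_duplicate_ids(self):
        with pytest.raises(ValueError, match="missing"):
            sosa.ExpressionMatrix(np.array([[1.0, np.nan], [0, 1]]), ["a", "b"], ["g1", "g2"])
        with pytest.raises(ValueError, match="duplicate gene"):
            sosa.ExpressionMatrix(np.ones((2, 2)), ["a", "b"], ["g", "g"])
        with pytest.raises(ValueError, match="at least 2 samples"):
            sosa.ExpressionMatrix(np.ones((1, 2)), ["a"], ["g1", "g2"])

    def test_design_invariants(self):
        G = make_groups([2, 2])
        with pytest.raises(ValueError, match="exactly one group"):
            sosa.FactorDesign(G=np.array([[1.0, 1.0], [0, 1], [1, 0], [0, 1]]),
                              group_labels=["a", "b"])
        with pytest.raises(ValueError, match="requires an outcome"):
            sosa.FactorDesign(G=G, group_labels=["a", "b"], mode="supervised")
        with pytest.raises(ValueError, match="rows"):
            sosa.FactorDesign(G=G, group_labels=["a", "b"],
                              Y=np.ones((3, 1)), mode="supervised")


class TestKnownFactorMatrix:
    def test_unsupervised_returns_g(self):
        G = make_groups([2, 2])
        design = sosa.FactorDesign(G=G, group_labels=["a", "b"])
        known = sosa.build_known_factor_matrix(design)
        assert np.array_equal(known.matrix, G)
        assert known.rank == 2 and known.dropped_columns == []

    def test_collinear_indicator_column_dropped(self):
        # Y (2-class indicator) + G (2 groups): columns sum to the all-ones
        # vector twice, so exactly one column is redundant
        G = make_groups([2, 2])
        Y = np.array([[1.0, 0], [0, 1], [1, 0], [0, 1]])
        design = sosa.FactorDesign(G=G, group_labels=["a", "b"], Y=Y, mode="supervised")
        known = sosa.build_known_factor_matrix(design)
        full = np.hstack([Y, G])
        assert np.linalg.matrix_rank(full) == 3  # brute-force oracle via SVD
        assert known.rank == 3
        assert len(known.dropped_columns) == 1
        assert np.linalg.matrix_rank(known.matrix) == known.matrix.shape[1]

    def test_supervised_shape_bound(self):
        rng = np.random.default_rng(0)
        G = make_groups([4, 3, 3])
        Y = np.zeros((10, 2))
        Y[np.arange(10), rng.integers(0, 2, 10)] = 1
        Y[0], Y[1] = [1, 0], [0, 1]
        design = sosa.FactorDesign(G=G, group_labels=list("abc"), Y=Y, mode="supervised")
        known = sosa.build_known_factor_matrix(design)
        assert known.matrix.shape[1] <= 5
        assert known.rank == known.matrix.shape[1]


class TestResidualProjector:
    def test_ones_column_gives_centering_matrix(self):
        R = sosa.residual_projector(np.ones((3, 1)))
        expected = np.eye(3) - np.full((3, 3), 1.0 / 3.0)
        np.testing.assert_allclose(R.matrix, expected, atol=1e-12)

    def test_full_rank_square_gives_zero(self):
        N = np.linalg.qr(np.random.default_rng(1).normal(size=(4, 4)))[0]
        R = sosa.residual_projector(N)
        assert np.max(np.abs(R.matrix)) < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_projector_algebra(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(4, 50), rng.integers(1, 4)
        N = rng.normal(size=(n, k))
        R = sosa.residual_projector(N).matrix
        # independent check against scipy's pseudoinverse
        R_oracle = np.eye(n) - N @ scipy.linalg.pinv(N)
        np.testing.assert_allclose(R, R_oracle, atol=1e-10)
        assert np.max(np.abs(R @ R - R)) < 1e-10
        assert np.max(np.abs(R - R.T)) < 1e-10
        assert np.max(np.abs(R @ N)) < 1e-10

    def test_near_collinear_columns_handled(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(8, 1))
        N = np.hstack([v, v * (1 + 1e-14), rng.normal(size=(8, 1))])
        R = sosa.residual_projector(N)
        assert R.source_rank == 2
        assert np.max(np.abs(R.matrix @ N)) < 1e-8

    def test_errors(self):
        with pytest.raises(ValueError):
            sosa.residual_projector(np.empty((5, 0)))
        with pytest.raises(ValueError):
            sosa.residual_projector(np.ones((1, 1)))


class TestExtractSurrogates:
    def test_k_zero_is_valid_and_empty(self, small_spike_in):
        X, design, _ = small_spike_in
        R = sosa.residual_projector(design.G)
        s = sosa.extract_surrogates(X, R, 0)
        assert s.K == 0 and s.H.shape == (X.n_samples, 0)

    def test_rank_one_residual_recovered_exactly(self):
        rng = np.random.default_rng(3)
        n, p = 12, 30
        G = make_groups([6, 6])
        R = sosa.residual_projector(G)
        direction = R.matrix @ rng.normal(size=n)
        X = np.outer(direction, rng.normal(size=p))
        Xm = sosa.ExpressionMatrix(X + 5.0, [f"s{i}" for i in range(n)],
                                   [f"g{j}" for j in range(p)])
        s = sosa.extract_surrogates(Xm, R, 1)
        cor = np.corrcoef(s.H[:, 0], direction)[0, 1]
        assert abs(cor) > 1 - 1e-10

    def test_two_planted_factors_span_recovered(self):
        cfg = sosa.SimConfig(n_samples=60, n_genes=500, n_groups=3, group_effect=1.0,
                             k_latent=2, latent_scale=3.0, noise_sd=1.0,
                             n_signal_genes=0, seed=7)
        X, design, truth = sosa.simulate_dataset(cfg)
        R = sosa.residual_projector(design.G)
        s = sosa.extract_surrogates(X, R, 2)
        # canonical correlations between span(H) and span(R_N F_true)
        Qa = np.linalg.qr(s.H)[0]
        Qb = np.linalg.qr(R.matrix @ truth.F_true)[0]
        cc = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
        assert np.all(cc >= 0.95)

    def test_full_rank_reproduces_svd_basis(self):
        rng = np.random.default_rng(4)
        n, p = 10, 20
        G = make_groups([5, 5])
        R = sosa.residual_projector(G)
        X = rng.normal(size=(n, p))
        resid = R.matrix @ X
        rank = np.linalg.matrix_rank(resid)
        s = sosa.extract_surrogates(X, R, rank)
        u = np.linalg.svd(resid, full_matrices=False)[0][:, :rank]
        # columns agree up to the deterministic sign convention
        dots = np.abs(np.sum(s.H * u, axis=0))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_k_beyond_rank_errors(self, small_spike_in):
        X, design, _ = small_spike_in
        R = sosa.residual_projector(design.G)
        with pytest.raises(ValueError, match="at most"):
            sosa.extract_surrogates(X, R, X.n_samples + 1)

    def test_deterministic_sign(self, small_spike_in):
        X, design, _ = small_spike_in
        R = sosa.residual_projector(design.G)
        H1 = sosa.extract_surrogates(X, R, 3).H
        H2 = sosa.extract_surrogates(X, R, 3).H
        assert np.array_equal(H1, H2)
        assert np.all(H1[np.argmax(np.abs(H1), axis=0), np.arange(3)] > 0)


class TestEstimateUnknownFactor:
    def test_fixed_point(self):
        rng = np.random.default_rng(5)
        n, p = 15, 8
        X = rng.normal(size=(n, p))
        sub = X - X.mean(axis=0)
        e1 = np.linalg.svd(sub, full_matrices=False)[0][:, 0]
        F_k, j_star, cor, sel = sosa.estimate_unknown_factor(X, e1, m=p)
        assert j_star == 0
        assert cor > 1 - 1e-10
        assert abs(abs(np.dot(F_k, e1)) - 1) < 1e-10

    def test_m_equals_p_uses_full_matrix(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 10))
        h = rng.normal(size=20)
        F_k, _, _, sel = sosa.estimate_unknown_factor(X, h, m=10)
        assert sel == list(range(10))

    def test_planted_factor_recovered(self):
        rng = np.random.default_rng(11)
        n, p = 40, 500
        f = rng.normal(size=n)
        f = (f - f.mean()) / f.std()
        load = np.zeros(p)
        load[:50] = 5.0 * rng.choice([-1, 1], 50) * rng.uniform(0.8, 1.2, 50)
        X = np.outer(f, load) + rng.normal(0, 1, (n, p))
        h = f + 0.05 * rng.normal(size=n)  # noisy surrogate
        F_k, _, _, _ = sosa.estimate_unknown_factor(X, h, m=100)
        assert abs(np.corrcoef(F_k, f)[0, 1]) >= 0.99

    def test_constant_surrogate_and_bad_m(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        with pytest.raises(ValueError, match="constant"):
            sosa.estimate_unknown_factor(X, np.ones(6), m=2)
        with pytest.raises(ValueError, match="m must be"):
            sosa.estimate_unknown_factor(X, np.arange(6.0), m=9)

    def test_constant_columns_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 5))
        X[:, 2] = 3.0
        h = rng.normal(size=10)
        with pytest.warns(UserWarning, match="constant"):
            _, _, _, sel = sosa.estimate_unknown_factor(X, h, m=5)
        assert 2 not in sel

    def test_correlation_helper_zeroes_constant_columns(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        r = _pearson_with_vector(X, np.arange(5.0))
        assert r[0] == pytest.approx(1.0)
        assert r[1] == 0.0


class TestBuildAdjusted:
    def test_orthogonal_nuisance_leaves_x_untouched(self):
        n, p = 12, 6
        M = make_groups([6, 6])
        U = np.zeros((n, 1))
        U[:6, 0], U[6:, 0] = np.array([1, -1, 1, -1, 1, -1]), np.array([1, -1, 1, -1, 1, -1])
        beta = np.random.default_rng(8).normal(size=(2, p))
        X = M @ beta
        adj = sosa.build_adjusted(X, M, U)
        np.testing.assert_allclose(adj.alpha_hat, 0, atol=1e-10)
        np.testing.assert_allclose(adj.X_a, X, atol=1e-10)

    def test_no_nuisance_identity(self, small_spike_in):
        X, design, _ = small_spike_in
        adj = sosa.build_adjusted(X, design.G, np.empty((X.n_samples, 0)))
        assert np.array_equal(adj.X_a, X.values)

    def test_ols_recovery_seeded(self):
        rng = np.random.default_rng(3)
        n, p, u = 60, 200, 2
        M = np.zeros((n, 3))
        M[np.arange(n), np.arange(n) % 3] = 1
        U = rng.normal(size=(n, u))
        beta = rng.normal(size=(3, p))
        alpha = rng.normal(size=(u, p))
        eps = rng.normal(0, 0.1, (n, p))
        X = M @ beta + U @ alpha + eps
        adj = sosa.build_adjusted(X, M, U)
        # direct lstsq oracle on the same draw
        coef = np.linalg.lstsq(np.hstack([M, U]), X, rcond=None)[0]
        np.testing.assert_allclose(adj.alpha_hat, coef[3:], atol=1e-10)
        assert np.max(np.abs(adj.alpha_hat - alpha)) < 0.5  # ~5 sigma OLS error
        target = M @ beta + eps
        rel = np.linalg.norm(adj.X_a - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_interest_nuisance_collision_errors(self):
        M = make_groups([3, 3])
        U = M[:, :1].copy()  # collides with interest space
        X = np.random.default_rng(9).normal(size=(6, 4))
        with pytest.raises(ValueError, match="rank-deficient"):
            sosa.build_adjusted(X, M, U)


class TestStageOnePipeline:
    def test_adjustment_improves_interest_correlation(self):
        """On supervised draws with latent confounding, X_a tracks the
        outcome-plus-noise component better than raw X on average."""
        gains = []
        for seed in range(5):
            cfg = sosa.SimConfig(n_samples=60, n_genes=150, n_groups=3,
                                 group_effect=1.5, n_classes=2, outcome_effect=1.0,
                                 n_signal_genes=30, k_latent=2, latent_scale=2.0,
                                 noise_sd=1.0, factor_design_correlation=0.3,
                                 seed=seed)
            X, design, truth = sosa.simulate_dataset(cfg)
            target = truth.Y @ truth.gamma + truth.epsilon
            adj, _, _ = sosa.adjust_heterogeneity(X, design, K=2)

            def mean_cor(A):
                cors = []
                for j in range(A.shape[1]):
                    c = np.corrcoef(A[:, j], target[:, j])[0, 1]
                    if np.isfinite(c):
                        cors.append(c)
                return np.mean(cors)

            gains.append(mean_cor(adj.X_a) - mean_cor(X.values))
        assert np.mean(gains) > 0

    def test_supervised_nuisance_includes_batches(self):
        cfg = sosa.SimConfig(n_samples=40, n_genes=80, n_groups=4, n_classes=2,
                             group_effect=2.0, outcome_effect=1.5,
                             n_signal_genes=10, k_latent=1, latent_scale=1.0,
                             seed=0)
        X, design, _ = sosa.simulate_dataset(cfg)
        adj, surr, _ = sosa.adjust_heterogeneity(X, design, K=1)
        # [G | F] with one G column dropped for the indicator collinearity
        assert adj.U.shape[1] == design.G.shape[1] - 1 + 1
        assert adj.M.shape[1] == 2  # Y
        assert surr.F.shape == (40, 1)

    def test_deterministic(self, small_spike_in):
        X, design, _ = small_spike_in
        a1, s1, _ = sosa.adjust_heterogeneity(X, design, K=2)
        a2, s2, _ = sosa.adjust_heterogeneity(X, design, K=2)
        assert np.array_equal(a1.X_a, a2.X_a)
        assert np.array_equal(s1.F, s2.F)
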