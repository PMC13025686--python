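import numpy as np
import pytest
from scipy.optimize import minimize

from cigbls.bls_core import solve_ridge
from cigbls.graph_reg import (
    GraphRegularizer,
    build_anchor_regularizer,
    build_dense_lap_oracle,
    manifold_quadform,
    reduced_rank_regularizer,
    solve_dense_lap,
    solve_manifold,
)


def random_nonneg_H(rng, n=15, m=4):
    return rng.uniform(0.05, 1.0, size=(n, m))


class TestBuildAnchorRegularizer:
    def test_row_sums_of_similarity_are_one(self, rng):
        reg = build_anchor_regularizer(random_nonneg_H(rng), beta=0.1)
        S = reg.dense_similarity()
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-12)

    def test_hard_assignment_block_structure(self):
        # one nonzero per row: S_hat is constant within anchor groups
        H = np.zeros((6, 2))
        H[[0, 1, 2], 0] = 1.0
        H[[3, 4, 5], 1] = 2.0
        S = build_anchor_regularizer(H, 0.0).dense_similarity()
        expected = np.zeros((6, 6))
        expected[:3, :3] = 1.0 / 3.0
        expected[3:, 3:] = 1.0 / 3.0
        np.testing.assert_allclose(S, expected, atol=1e-14)

    def test_matches_explicit_dense_construction(self, rng):
        H = random_nonneg_H(rng, n=5, m=3)
        reg = build_anchor_regularizer(H, 0.0)
        H_bar = H / H.sum(axis=1, keepdims=True)
        delta = H_bar.sum(axis=0)
        expected = H_bar @ np.diag(1.0 / delta) @ H_bar.T
        np.testing.assert_allclose(reg.dense_similarity(), expected, rtol=1e-12)

    def test_all_zero_row_rejected(self, rng):
        H = random_nonneg_H(rng)
        H[3] = 0.0
        with pytest.raises(ValueError, match="all-zero row"):
            build_anchor_regularizer(H, 0.0)

    def test_negative_entries_rejected(self, rng):
        H = random_nonneg_H(rng)
        H[0, 0] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            build_anchor_regularizer(H, 0.0)

    def test_dead_anchor_floored_with_warning(self, rng):
        H = random_nonneg_H(rng)
        H[:, 2] = 0.0
        with pytest.warns(RuntimeWarning, match="dead anchors"):
            reg = build_anchor_regularizer(H, 0.0)
        assert np.all(reg.delta_diag > 0)


class TestReducedRankRegularizer:
    def test_equals_dense_laplacian_quadform(self, rng):
        A = rng.standard_normal((20, 7))
        H = random_nonneg_H(rng, n=20, m=5)
        reg = build_anchor_regularizer(H, 0.0)
        got = reduced_rank_regularizer(A, reg)
        L = np.eye(20) - reg.dense_similarity()
        np.testing.assert_allclose(got, A.T @ L @ A, rtol=1e-9, atol=1e-11)

    def test_symmetric_output(self, rng):
        A = rng.standard_normal((25, 6))
        reg = build_anchor_regularizer(random_nonneg_H(rng, 25, 4), 0.0)
        M = reduced_rank_regularizer(A, reg)
        np.testing.assert_allclose(M, M.T, atol=1e-10)

    def test_projector_limit_annihilates_span(self, rng):
        # orthonormal hard-assignment H_bar makes S_hat a projector on its span
        H = np.zeros((8, 2))
        H[:4, 0] = 1.0
        H[4:, 1] = 1.0
        reg = build_anchor_regularizer(H, 0.0)
        # columns of A inside span(blocks of constants) are annihilated
        A = np.zeros((8, 2))
        A[:4, 0] = 3.0
        A[4:, 1] = -2.0
        np.testing.assert_allclose(reduced_rank_regularizer(A, reg), 0.0, atol=1e-12)


def manifold_objective(A, Y, W, lam, L):
    R = A @ W - Y
    return float(np.sum(R**2) + lam * np.sum(W**2) + np.trace(W.T @ A.T @ L @ A @ W))


class TestSolveManifold:
    def test_beta_zero_reduces_to_ridge(self, rng):
        A = rng.standard_normal((30, 8))
        Y = rng.standard_normal((30, 2))
        reg = build_anchor_regularizer(random_nonneg_H(rng, 30, 5), 0.0)
        W_m = solve_manifold(A, Y, 0.01, reg).W
        W_r = solve_ridge(A, Y, 0.01).W
        np.testing.assert_allclose(W_m, W_r, rtol=1e-12, atol=1e-14)

    def test_matches_numerical_minimizer(self, rng):
        A = rng.standard_normal((12, 4))
        Y = rng.standard_normal((12, 1))
        beta, lam = 0.7, 0.05
        reg = build_anchor_regularizer(random_nonneg_H(rng, 12, 3), beta)
        L = beta * (np.eye(12) - reg.dense_similarity())
        W_star = solve_manifold(A, Y, lam, reg).W

        res = minimize(
            lambda w: manifold_objective(A, Y, w.reshape(4, 1), lam, L),
            np.zeros(4),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        np.testing.assert_allclose(W_star.ravel(), res.x, rtol=1e-5, atol=1e-7)

    def test_half_norm_at_beta_one_in_identity_limit(self, rng):
        # S_hat forced to zero, lambda = 0: W scales exactly as 1/(1+beta)
        A = rng.standard_normal((40, 8))
        Y = rng.standard_normal((40, 1))
        reg0 = GraphRegularizer(np.zeros((40, 4)), np.ones(4), 0.0)
        W0 = solve_manifold(A, Y, 0.0, reg0).W
        W1 = solve_manifold(A, Y, 0.0, reg0.with_beta(1.0)).W
        assert np.linalg.norm(W1) / np.linalg.norm(W0) == pytest.approx(0.5, rel=1e-12)

    def test_monotone_smoothing_in_beta(self, rng):
        A = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 1))
        reg = build_anchor_regularizer(random_nonneg_H(rng, 30, 4), 0.0)
        L = np.eye(30) - reg.dense_similarity()
        penalties = []
        for beta in (0.0, 0.01, 0.1, 0.5, 1.0, 5.0):
            W = solve_manifold(A, Y, 1e-3, reg.with_beta(beta)).W
            penalties.append(float(np.trace(W.T @ A.T @ L @ A @ W)))
        assert all(a >= b - 1e-10 for a, b in zip(penalties, penalties[1:]))


class TestDenseLapOracle:
    def test_full_k_gives_complete_graph(self, rng):
        X = rng.standard_normal((7, 2))
        g = build_dense_lap_oracle(X, k_neighbors=6)
        off_diag = g.adjacency[~np.eye(7, dtype=bool)]
        assert np.all(off_diag == 1)

    def test_laplacian_row_sums_zero(self, rng):
        g = build_dense_lap_oracle(rng.standard_normal((10, 3)), k_neighbors=3)
        np.testing.assert_allclose(g.laplacian.sum(axis=1), 0.0, atol=1e-12)

    def test_adjacency_symmetric_or_rule(self, rng):
        g = build_dense_lap_oracle(rng.standard_normal((12, 2)), k_neighbors=2)
        np.testing.assert_array_equal(g.adjacency, g.adjacency.T)

    def test_trace_form_equals_double_sum(self, rng):
        # Tr(Y^T L Y) = 0.5 * sum_pq S_pq ||y_p - y_q||^2 on N=8
        X = rng.standard_normal((8, 2))
        g = build_dense_lap_oracle(X, k_neighbors=3)
        Y_hat = rng.standard_normal((8, 2))
        double_sum = 0.0
        for p in range(8):
            for q in range(8):
                double_sum += 0.5 * g.weights[p, q] * np.sum((Y_hat[p] - Y_hat[q]) ** 2)
        assert manifold_quadform(g.laplacian, Y_hat) == pytest.approx(double_sum, rel=1e-10)

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            build_dense_lap_oracle(rng.standard_normal((5, 2)), k_neighbors=5)


class TestSolveDenseLap:
    def test_beta_zero_is_ridge(self, rng):
        A = rng.standard_normal((10, 4))
        Y = rng.standard_normal((10, 1))
        g = build_dense_lap_oracle(rng.standard_normal((10, 3)), 3)
        np.testing.assert_allclose(
            solve_dense_lap(A, Y, 0.1, 0.0, g).W, solve_ridge(A, Y, 0.1).W, rtol=1e-12
        )

    def test_matches_numerical_minimizer(self, rng):
        A = rng.standard_normal((10, 4))
        Y = rng.standard_normal((10, 1))
        g = build_dense_lap_oracle(rng.standard_normal((10, 3)), 3)
        beta, lam = 0.4, 0.02
        W_star = solve_dense_lap(A, Y, lam, beta, g).W
        res = minimize(
            lambda w: manifold_objective(A, Y, w.reshape(4, 1), lam, beta * g.laplacian),
            np.zeros(4),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        np.testing.assert_allclose(W_star.ravel(), res.x, rtol=1e-5, atol=1e-7)

    def test_reduced_rank_equivalence_with_anchor_laplacian(self, rng):
        # the key identity: anchor solver == dense solver on L = I - S_hat
        A = rng.standard_normal((25, 6))
        Y = rng.standard_normal((25, 2))
        reg = build_anchor_regularizer(random_nonneg_H(rng, 25, 4), 0.8)
        L = np.eye(25) - reg.dense_similarity()
        W_fast = solve_manifold(A, Y, 1e-3, reg).W
        W_dense = solve_dense_lap(A, Y, 1e-3, 0.8, L).W
        np.testing.assert_allclose(W_fast, W_dense, rtol=1e-10, atol=1e-12)


def test_no_quadratic_allocation_in_anchor_path():
    """Fitting at N=10^4 must never allocate an N x N intermediate."""
    import tracemalloc

    from cigbls.experiments import default_model_config
    from cigbls.pipeline import WindowedDesign, fit_cigbls

    n = 10_000
    rng = np.random.default_rng(0)
    X = rng.uniform(size=(n, 4))
    y = rng.standard_normal((n, 1))
    design = WindowedDesign(X, y, np.zeros(n, dtype=object), ("a", "b", "c", "d"))
    config = default_model_config(0, nodes_per_channel=6, anchors_per_channel=6)
    tracemalloc.start()
    fit_cigbls(design, config)
    _, peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()
    assert peak < n * n * 8 / 4  # far below one float64 N x N matrix
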