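"""Kronecker parametric inverse regression: least squares and MLE."""

import numpy as np
import pytest

from kronsdr import (
    MatrixDataset,
    build_fourier,
    fit_kpir_ls,
    fit_kpir_mle,
    fit_ols_unconstrained,
    kron,
    loglik,
    update_delta_mle,
)
from kronsdr.kron import KroneckerMean
from kronsdr.simulate import ContinuousSimConfig, generate_continuous


class TestOls:
    def test_noiseless_recovery(self, noiseless_continuous):
        data, truth, design = noiseless_continuous
        B = fit_ols_unconstrained(data, design)
        np.testing.assert_allclose(B.T, truth.product, atol=1e-10)

    def test_fitted_values_are_projection(self, small_continuous):
        data, _, design = small_continuous
        B = fit_ols_unconstrained(data, design)
        X = data.vectorized()
        F = design.F
        P = F @ np.linalg.solve(F.T @ F, F.T)
        np.testing.assert_allclose(F @ B, P @ X, atol=1e-10)

    def test_pure_noise_coefficients_shrink(self, rng):
        data = MatrixDataset(rng.standard_normal((10000, 2, 2)),
                             rng.standard_normal(10000))
        design = build_fourier(data.y, 2, 1)
        B = fit_ols_unconstrained(data, design)
        assert np.linalg.norm(B) < 0.1

    def test_singular_design_raises(self, rng):
        data = MatrixDataset(rng.standard_normal((30, 2, 2)), np.full(30, 1.0))
        design = build_fourier(rng.standard_normal(30), 2, 1)
        design.F[:, 1] = design.F[:, 0]
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_ols_unconstrained(data, design)


class TestKpirLs:
    def test_exact_model_recovery(self, noiseless_continuous):
        data, truth, design = noiseless_continuous
        f = fit_kpir_ls(data, design)
        np.testing.assert_allclose(f.mean.product, truth.product, atol=1e-8)
        np.testing.assert_allclose(f.Delta_hat, 0.0, atol=1e-10)

    def test_delta_uses_residual_divisor(self, small_continuous):
        data, _, design = small_continuous
        f = fit_kpir_ls(data, design)
        D_mle = update_delta_mle(data, design, f.mean)
        ratio = (data.n - design.rank) / data.n
        np.testing.assert_allclose(D_mle, f.Delta_hat * ratio, atol=1e-10)

    def test_permutation_equivariance(self, small_continuous, rng):
        data, _, design = small_continuous
        f = fit_kpir_ls(data, design)
        perm = rng.permutation(data.n)
        data_p = MatrixDataset(data.X[perm], data.y[perm])
        design_p = build_fourier(data_p.y, design.k, design.r)
        f_p = fit_kpir_ls(data_p, design_p)
        np.testing.assert_allclose(f.mean.product, f_p.mean.product, atol=1e-12)
        np.testing.assert_allclose(f.Delta_hat, f_p.Delta_hat, atol=1e-12)

    def test_shift_invariance(self, small_continuous, rng):
        """Adding a constant matrix to every X_i changes nothing (centering)."""
        data, _, design = small_continuous
        shift = rng.standard_normal((data.p, data.T))
        data_s = MatrixDataset(data.X + shift, data.y)
        f = fit_kpir_ls(data, design)
        f_s = fit_kpir_ls(data_s, design)
        np.testing.assert_allclose(f.mean.product, f_s.mean.product, atol=1e-10)
        np.testing.assert_allclose(f.Delta_hat, f_s.Delta_hat, atol=1e-10)


class TestLoglik:
    def test_standard_normal_at_zero(self):
        # one scalar observation, centered to zero, unit variance, zero mean term
        data = MatrixDataset(np.zeros((1, 1, 1)), np.array([0.5]))
        design = type("D", (), {"F": np.zeros((1, 1)), "k": 1, "r": 1,
                                "rank": 0, "n": 1})()
        mean = KroneckerMean(np.zeros((1, 1)), np.zeros((1, 1)))
        val = loglik(data, design, mean, np.eye(1))
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_dense_inverse_oracle(self, rng):
        n, p, T = 12, 3, 2
        data = MatrixDataset(rng.standard_normal((n, p, T)), rng.standard_normal(n))
        design = build_fourier(data.y, 2, 1)
        mean = KroneckerMean(rng.standard_normal((T, 1)), rng.standard_normal((p, 2)))
        A = rng.standard_normal((p * T, p * T))
        Delta = A @ A.T + p * T * np.eye(p * T)
        val = loglik(data, design, mean, Delta)
        # naive dense-inverse implementation
        W = kron(mean.alpha, mean.beta)
        Xv = data.vectorized()
        Di = np.linalg.inv(Delta)
        quad = sum(
            (Xv[i] - W @ design.F[i]) @ Di @ (Xv[i] - W @ design.F[i])
            for i in range(n)
        )
        ref = (-0.5 * n * p * T * np.log(2 * np.pi)
               - 0.5 * n * np.log(np.linalg.det(Delta)) - 0.5 * quad)
        assert val == pytest.approx(ref, abs=1e-8)

    def test_inflating_delta_lowers_loglik_at_perfect_fit(self, noiseless_continuous):
        data, truth, design = noiseless_continuous
        mean = KroneckerMean(truth.alpha, truth.beta)
        base = loglik(data, design, mean, np.eye(data.p * data.T))
        worse = loglik(data, design, mean, 2.0 * np.eye(data.p * data.T))
        assert worse < base

    def test_non_pd_delta_rejected(self, small_continuous):
        data, _, design = small_continuous
        mean = KroneckerMean(np.zeros((data.T, 2)), np.zeros((data.p, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            loglik(data, design, mean, -np.eye(data.p * data.T))


class TestDeltaUpdate:
    def test_zero_mean_gives_second_moment(self, small_continuous):
        data, _, design = small_continuous
        mean = KroneckerMean(np.zeros((data.T, design.r)), np.zeros((data.p, design.k)))
        D = update_delta_mle(data, design, mean)
        Xv = data.vectorized()
        np.testing.assert_allclose(D, Xv.T @ Xv / data.n, atol=1e-10)

    def test_perfect_fit_gives_zero(self, noiseless_continuous):
        data, truth, design = noiseless_continuous
        D = update_delta_mle(data, design, KroneckerMean(truth.alpha, truth.beta))
        np.testing.assert_allclose(D, 0.0, atol=1e-12)


class TestKpirMle:
    def test_noiseless_converges_to_truth(self, noiseless_continuous):
        data, truth, design = noiseless_continuous
        f = fit_kpir_mle(data, design, ridge=1e-8)
        np.testing.assert_allclose(f.mean.product, truth.product, atol=1e-4)
        assert f.converged

    def test_loglik_trace_non_decreasing(self):
        for seed in range(5):
            cfg = ContinuousSimConfig(n=150, p=3, T=3, k=2, r=2, d1=2, d2=2,
                                      noise_scale=1.0, seed=seed)
            data, _ = generate_continuous(cfg)
            design = build_fourier(data.y, 2, 2)
            f = fit_kpir_mle(data, design)
            assert np.all(np.diff(f.loglik_trace) > -1e-6 * np.abs(f.loglik_trace[0]))

    def test_gradient_matches_finite_differences(self, small_continuous):
        from scipy.optimize import check_grad
        from kronsdr.kpir import _Stats, nkp_rearrange

        data, _, design = small_continuous
        st = _Stats(data, design)
        T, p, k, r = data.T, data.p, design.k, design.r
        Di = np.eye(p * T)
        DiC = Di @ st.C
        n_a = T * r

        def fun(theta):
            a = theta[:n_a].reshape(T, r)
            b = theta[n_a:].reshape(p, k)
            W = kron(a, b)
            return 0.5 * (-2 * np.sum(W * DiC) + np.sum((W.T @ (Di @ W)) * st.G))

        def grad(theta):
            a = theta[:n_a].reshape(T, r)
            b = theta[n_a:].reshape(p, k)
            W = kron(a, b)
            S = Di @ W @ st.G - DiC
            RS = nkp_rearrange(S, (T, r, p, k))
            return np.concatenate([(RS @ b.ravel()), (RS.T @ a.ravel())])

        theta0 = np.random.default_rng(1).standard_normal(n_a + p * k)
        assert check_grad(fun, grad, theta0) < 1e-5 * max(1.0, np.abs(fun(theta0)))

    def test_refuses_singular_regime_without_ridge(self, rng):
        data = MatrixDataset(rng.standard_normal((10, 3, 4)), rng.standard_normal(10))
        design = build_fourier(data.y, 2, 1)
        with pytest.raises(ValueError, match="ridge"):
            fit_kpir_mle(data, design)
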