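"""Kronecker principal fitted components: decomposition, subspace MLE, variants."""

import numpy as np
import pytest

from kronsdr import (
    MatrixDataset,
    build_binary,
    build_fourier,
    estimate_gamma_coeff,
    estimate_gamma_subspace,
    fit_kpfc,
    fit_kpir_ls,
    kron,
    pfc_decompose,
    projection_distance,
    reduce,
    sdr_from_kpir,
)
from kronsdr.kpfc import fmsdr_basis
from kronsdr.kron import SubspaceBasis, vlp_approx
from kronsdr.simulate import BinarySimConfig, generate_binary


class TestDecomposition:
    def test_res_plus_fit_identity(self, small_continuous):
        data, _, design = small_continuous
        dec = pfc_decompose(data, design, d=4)
        Xv = data.vectorized()
        np.testing.assert_allclose(
            dec.Delta_res + dec.Delta_fit, Xv.T @ Xv / data.n, atol=1e-10
        )

    def test_full_rank_d_gives_delta_res(self, small_continuous):
        """With d = k*r the covariance MLE reduces to the residual covariance."""
        data, _, design = small_continuous
        dec = pfc_decompose(data, design, d=design.ncol)
        np.testing.assert_allclose(dec.Delta_mle, dec.Delta_res, atol=1e-8)
        assert np.all(dec.K_hat[: dec.d] == 0)

    def test_eigenvalues_sorted_and_psd(self, small_continuous):
        data, _, design = small_continuous
        dec = pfc_decompose(data, design, d=2)
        assert np.all(np.diff(dec.lambda_hat) <= 1e-12)
        w = np.linalg.eigvalsh(dec.Delta_mle)
        assert w[0] >= -1e-8 * np.linalg.norm(dec.Delta_mle)
        np.testing.assert_allclose(dec.Delta_mle, dec.Delta_mle.T, atol=1e-10)

    def test_pure_noise_fit_covariance_small(self, rng):
        data = MatrixDataset(rng.standard_normal((4000, 2, 2)),
                             rng.standard_normal(4000))
        design = build_fourier(data.y, 2, 1)
        dec = pfc_decompose(data, design, d=1)
        assert np.linalg.norm(dec.Delta_fit) < 0.1 * np.linalg.norm(dec.Delta_res)

    def test_singular_regime_needs_ridge(self, rng):
        data = MatrixDataset(rng.standard_normal((8, 3, 3)), rng.standard_normal(8))
        design = build_fourier(data.y, 2, 1)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            pfc_decompose(data, design, d=1)
        dec = pfc_decompose(data, design, d=1, ridge=1e-3)
        assert np.linalg.eigvalsh(dec.Delta_res)[0] > 0


class TestGammaSubspace:
    def test_noiseless_recovers_true_span(self, noiseless_continuous):
        data, truth, design = noiseless_continuous
        dec = pfc_decompose(data, design, d=4, ridge=1e-10)
        G = estimate_gamma_subspace(dec, 4)
        true_span = kron(truth.Gamma1, truth.Gamma2)
        assert projection_distance(G, true_span) < 1e-6

    def test_scale_invariance(self, small_continuous):
        data, _, design = small_continuous
        G1 = estimate_gamma_subspace(pfc_decompose(data, design, d=2), 2)
        data2 = MatrixDataset(2.0 * data.X, data.y)
        G2 = estimate_gamma_subspace(pfc_decompose(data2, design, d=2), 2)
        assert projection_distance(G1, G2) < 1e-8

    def test_full_dimension_is_identity_projection(self, rng):
        data = MatrixDataset(rng.standard_normal((60, 2, 2)), rng.standard_normal(60))
        design = build_fourier(data.y, 2, 2)
        dec = pfc_decompose(data, design, d=4)
        G = estimate_gamma_subspace(dec, 4)
        np.testing.assert_allclose(G.projection(), np.eye(4), atol=1e-8)


class TestGammaCoeff:
    def test_exact_gls_recovery(self, small_continuous, rng):
        data, _, design = small_continuous
        dec = pfc_decompose(data, design, d=2)
        G = estimate_gamma_subspace(dec, 2)
        g0 = rng.standard_normal((2, design.ncol))
        got = estimate_gamma_coeff(G, dec.Delta_mle, G.matrix @ g0)
        np.testing.assert_allclose(got, g0, atol=1e-10)

    def test_identity_metric_is_orthogonal_projection(self, rng):
        G = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        B_T = rng.standard_normal((8, 3))
        got = estimate_gamma_coeff(G, np.eye(8), B_T)
        np.testing.assert_allclose(got, G.T @ B_T, atol=1e-10)

    def test_residual_is_metric_orthogonal(self, small_continuous, rng):
        data, _, design = small_continuous
        dec = pfc_decompose(data, design, d=2)
        G = estimate_gamma_subspace(dec, 2)
        B_T = rng.standard_normal((data.p * data.T, design.ncol))
        gam = estimate_gamma_coeff(G, dec.Delta_mle, B_T)
        resid = B_T - G.matrix @ gam
        Di = np.linalg.inv(dec.Delta_mle)
        np.testing.assert_allclose(G.matrix.T @ Di @ resid, 0.0, atol=1e-8)


class TestFitKpfc:
    @pytest.mark.parametrize("variant", ["kpfc1", "kpfc2", "kpfc3"])
    def test_noiseless_recovers_span(self, noiseless_continuous, variant):
        data, truth, design = noiseless_continuous
        f = fit_kpfc(data, design, dims=(2, 2, 2, 2), variant=variant, ridge=1e-10)
        true_span = kron(truth.Gamma1, truth.Gamma2)
        assert projection_distance(kron(f.Gamma1, f.Gamma2), true_span) < 1e-6
        np.testing.assert_allclose(
            f.Gamma1.T @ f.Gamma1, np.eye(2), atol=1e-10
        )
        np.testing.assert_allclose(
            f.Gamma2.T @ f.Gamma2, np.eye(2), atol=1e-10
        )

    def test_kpfc2_equals_kpfc3_for_rank_one(self, binary_data):
        """With k = r = d1 = d2 = 1 the gamma split is exact, so the two
        variants coincide."""
        data, _ = binary_data
        design = build_binary(data.y)
        f2 = fit_kpfc(data, design, dims=(1, 1, 1, 1), variant="kpfc2")
        f3 = fit_kpfc(data, design, dims=(1, 1, 1, 1), variant="kpfc3")
        np.testing.assert_allclose(f2.mean_product, f3.mean_product, atol=1e-10)

    def test_dimension_check(self, small_continuous):
        data, _, design = small_continuous
        with pytest.raises(ValueError, match="exceeds"):
            fit_kpfc(data, design, dims=(3, 2, 2, 2))

    def test_kronecker_factor_span_identity(self, rng):
        """For an exactly-Kronecker basis the VLP-factored span matches."""
        G1 = np.linalg.qr(rng.standard_normal((4, 2)))[0]
        G2 = np.linalg.qr(rng.standard_normal((3, 1)))[0]
        G = kron(G1, G2)
        km, res = vlp_approx(G, (4, 2, 3, 1))
        assert res < 1e-20
        assert projection_distance(kron(km.alpha, km.beta), G) < 1e-8


class TestReduce:
    def test_zero_at_mean(self, small_continuous):
        data, _, design = small_continuous
        f = fit_kpfc(data, design, dims=(2, 2, 2, 2))
        np.testing.assert_allclose(reduce(f, data.Xbar), 0.0, atol=1e-12)

    def test_affine_linearity(self, small_continuous, rng):
        data, _, design = small_continuous
        f = fit_kpfc(data, design, dims=(2, 2, 2, 2))
        X1 = rng.standard_normal((data.p, data.T))
        X2 = rng.standard_normal((data.p, data.T))
        a, b = 0.3, 0.5
        combo = a * X1 + b * X2 + (1 - a - b) * data.Xbar
        np.testing.assert_allclose(
            reduce(f, combo), a * reduce(f, X1) + b * reduce(f, X2), atol=1e-10
        )

    def test_group_separation_sign(self, binary_data):
        """Scores separate the two groups in the planted-shift direction."""
        data, _ = binary_data
        design = build_binary(data.y)
        f = sdr_from_kpir(fit_kpir_ls(data, design), 1, 1)
        s = reduce(f, data.X).ravel()
        assert abs(s[data.y == 1].mean() - s[data.y == 0].mean()) > 3 * s.std() / np.sqrt(data.n)

    def test_shape_mismatch(self, small_continuous):
        data, _, design = small_continuous
        f = fit_kpfc(data, design, dims=(2, 2, 2, 2))
        with pytest.raises(ValueError, match="expected"):
            reduce(f, np.zeros((data.p + 1, data.T)))


def test_fmsdr_basis_definition(rng):
    G1 = np.linalg.qr(rng.standard_normal((3, 1)))[0]
    G2 = np.linalg.qr(rng.standard_normal((4, 2)))[0]
    A = rng.standard_normal((12, 12))
    Delta = A @ A.T + 12 * np.eye(12)
    basis = fmsdr_basis(G1, G2, Delta)
    np.testing.assert_allclose(
        Delta @ basis.matrix, kron(G1, G2), atol=1e-10
    )
    assert isinstance(basis, SubspaceBasis)
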