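"""Comparator methods: (2D)^2 PCA/PCR and longitudinal SIR (LSIR).

(2D)^2 PCA computes separate eigenbases of the sample row and column
covariance matrices of the matrix predictors; regressing the response on
the retained two-sided principal components gives (2D)^2 PCR.  LSIR is the
Kronecker-structured analogue of sliced inverse regression / linear
discriminant analysis: it slices the response, estimates a separable
within-slice covariance by a one-pass moment (flip-flop style) estimator,
and scales the leading Kronecker component of the between-slice means by
the inverse covariance factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .dataset import MatrixDataset
from .kron import (
    SubspaceBasis,
    fix_sign_columns,
    kron,
    vlp_approx,
)


@dataclass
class TwoDPcaFit:
    U_alpha: np.ndarray        # T x T column-eigenvectors
    U_beta: np.ndarray         # p x p row-eigenvectors
    Sigma_alpha_hat: np.ndarray
    Sigma_beta_hat: np.ndarray
    eigvals_alpha: np.ndarray
    eigvals_beta: np.ndarray
    d1: int
    d2: int
    Xbar: np.ndarray

    @property
    def kron_mean_estimate(self) -> np.ndarray:
        """(2D)^2 PCA estimate of alpha (x) beta: U_alpha[:, :d1] (x) U_beta[:, :d2]."""
        return kron(self.U_alpha[:, : self.d1], self.U_beta[:, : self.d2])

    def components(self, X: np.ndarray) -> np.ndarray:
        """Two-sided PCs ``U_beta^T (X - Xbar) U_alpha`` for a stack of matrices."""
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 2
        if squeeze:
            X = X[None]
        Xc = X - self.Xbar
        out = np.einsum("ji,njk,kl->nil", self.U_beta, Xc, self.U_alpha)
        return out[0] if squeeze else out


def _eigh_desc(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, V = linalg.eigh((S + S.T) / 2.0)
    order = np.argsort(-w, kind="stable")
    return w[order], fix_sign_columns(V[:, order])


def fit_2d2pca(data: MatrixDataset, d1: int | None = None, d2: int | None = None) -> TwoDPcaFit:
    """Row and column eigenbases of the centered matrix predictors."""
    if data.n < 2:
        raise ValueError("need at least two samples")
    d1 = data.T if d1 is None else d1
    d2 = data.p if d2 is None else d2
    Xc = data.X - data.Xbar
    Sa = np.einsum("nji,njk->ik", Xc, Xc) / data.n   # T x T column covariance
    Sb = np.einsum("nij,nkj->ik", Xc, Xc) / data.n   # p x p row covariance
    wa, Ua = _eigh_desc(Sa)
    wb, Ub = _eigh_desc(Sb)
    return TwoDPcaFit(
        U_alpha=Ua, U_beta=Ub, Sigma_alpha_hat=Sa, Sigma_beta_hat=Sb,
        eigvals_alpha=wa, eigvals_beta=wb, d1=d1, d2=d2, Xbar=data.Xbar,
    )


def predict_2d2pcr(
    fit: TwoDPcaFit,
    data: MatrixDataset,
    d1: int | None = None,
    d2: int | None = None,
    X_new: np.ndarray | None = None,
):
    """OLS of the response on the retained two-sided PCs.

    Returns ``(coef, fitted_scores)``; with ``X_new`` the scores are for
    the new matrices instead.  The coefficient vector includes the
    intercept as its first entry; a rank-deficient PC design falls back to
    the least-norm solution with a warning.
    """
    d1 = fit.d1 if d1 is None else d1
    d2 = fit.d2 if d2 is None else d2
    if d1 * d2 >= data.n:
        raise ValueError("d1*d2 must be smaller than the sample size")
    Z = fit.components(data.X)[:, :d2, :d1].reshape(data.n, -1)
    D = np.column_stack([np.ones(data.n), Z])
    coef, _, rank, _ = np.linalg.lstsq(D, data.y, rcond=None)
    if rank < D.shape[1]:
        warnings.warn("collinear principal components: least-norm OLS solution")
    if X_new is None:
        return coef, D @ coef
    Zn = fit.components(X_new)
    if Zn.ndim == 2:
        Zn = Zn[None]
    Zn = Zn[:, :d2, :d1].reshape(Zn.shape[0], -1)
    return coef, np.column_stack([np.ones(Zn.shape[0]), Zn]) @ coef


@dataclass
class LsirFit:
    Gamma1: np.ndarray          # T x 1 direction of the time factor
    Gamma2: np.ndarray          # p x 1 direction of the variable factor
    Sigma1_hat: np.ndarray      # T x T within-slice time covariance
    Sigma2_hat: np.ndarray      # p x p within-slice variable covariance
    direction: SubspaceBasis    # pT x 1 FMSDR direction
    Xbar: np.ndarray
    degenerate: bool = False

    def scores(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        squeeze = X_new.ndim == 2
        if squeeze:
            X_new = X_new[None]
        Xc = X_new - self.Xbar
        V = Xc.transpose(0, 2, 1).reshape(X_new.shape[0], -1)
        s = (V @ self.direction.matrix).ravel()
        return s[0] if squeeze else s


def _slice_indices(y: np.ndarray, n_slices: int) -> list[np.ndarray]:
    classes = np.unique(y)
    if classes.size <= n_slices and np.allclose(classes, classes.astype(int)):
        groups = [np.flatnonzero(y == c) for c in classes]
    else:
        order = np.argsort(y, kind="stable")
        groups = [g for g in np.array_split(order, n_slices)]
    for g in groups:
        if g.size == 0:
            raise ValueError("empty slice: reduce n_slices")
    return groups


def fit_lsir(data: MatrixDataset, n_slices: int = 10) -> LsirFit:
    """Longitudinal SIR: Kronecker LDA direction for matrix predictors.

    Slices are the classes for a categorical response, or equal-frequency
    groups for a continuous one.  Within-slice residuals give moment
    estimates of the separable covariance factors; the leading Kronecker
    component ``b a^T`` of the between-slice mean differences is scaled to
    the FMSDR direction ``(Sigma1^-1 a) (x) (Sigma2^-1 b)``.  A single
    direction (d = 1) is estimated.
    """
    groups = _slice_indices(data.y, n_slices)
    p, T = data.p, data.T
    M = np.stack([data.X[g].mean(axis=0) for g in groups])  # s x p x T
    Xbar = data.Xbar

    # within-slice moment estimates of the separable covariance factors
    R = data.X.copy()
    for s, g in enumerate(groups):
        R[g] -= M[s]
    Sigma2 = np.einsum("nij,nkj->ik", R, R) / (data.n * T)  # p x p
    Sigma1 = np.einsum("nji,njk->ik", R, R) / (data.n * p)  # T x T

    # between-slice signal: leading direction of the weighted centered slice
    # means, then its best Kronecker (rank-1) factorisation a (x) b
    w = np.array([g.size for g in groups]) / data.n
    N = np.column_stack(
        [np.sqrt(w[s]) * (M[s] - Xbar).T.ravel() for s in range(len(groups))]
    )  # pT x n_slices, columns sqrt(w_s) vec(M_s - Xbar)
    u, sv, _ = np.linalg.svd(N, full_matrices=False)
    degenerate = False
    data_scale = float(np.sqrt(np.einsum("nij,nij->", data.X - Xbar, data.X - Xbar) / data.n))
    if sv[0] < 1e-10 * max(data_scale, 1e-300):
        warnings.warn("equal slice means: LSIR direction is degenerate")
        degenerate = True
        a, b = np.ones(T), np.ones(p)
    else:
        km, _ = vlp_approx(u[:, :1], (T, 1, p, 1))
        a, b = km.alpha.ravel(), km.beta.ravel()

    g1 = np.linalg.solve(Sigma1, a)
    g2 = np.linalg.solve(Sigma2, b)
    g1 /= np.linalg.norm(g1)
    g2 /= np.linalg.norm(g2)
    direction = SubspaceBasis(kron(g1[:, None], g2[:, None]))
    return LsirFit(
        Gamma1=g1[:, None], Gamma2=g2[:, None],
        Sigma1_hat=Sigma1, Sigma2_hat=Sigma2,
        direction=direction, Xbar=Xbar, degenerate=degenerate,
    )
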