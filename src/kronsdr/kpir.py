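"""Kronecker parametric inverse regression (K-PIR).

The inverse regression of the vectorised predictors on the centered
response functions is an ordinary multivariate linear model; under the
Kronecker mean structure the coefficient matrix is ``(alpha (x) beta)^T``.
The least-squares estimator fits the unconstrained model and projects the
coefficient onto the Kronecker manifold with the nearest-Kronecker-product
(VLP) approximation.  The maximum-likelihood estimator assumes conditional
normality with constant covariance ``Delta`` and alternates a quasi-Newton
maximisation of the log-likelihood over ``(alpha, beta)`` with the
closed-form ``Delta`` update.

All computations run on the sufficient statistics ``F^T F``, ``X^T F`` and
``X^T X``, so iteration cost is independent of the sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .dataset import MatrixDataset
from .design import CenteredDesign
from .kron import KroneckerMean, apply_scale_convention, kron, nkp_rearrange, vlp_approx


@dataclass
class KpirFit:
    B_hat: np.ndarray          # (k*r) x (p*T) unconstrained OLS coefficients
    mean: KroneckerMean
    Delta_hat: np.ndarray      # pT x pT
    method: str                # "ls" | "mle"
    dims: tuple[int, int, int, int]  # (T, r, p, k)
    Xbar: np.ndarray
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iter: int = 0
    converged: bool = True


class _Stats:
    """Sufficient statistics of the centered inverse regression."""

    def __init__(self, data: MatrixDataset, design: CenteredDesign):
        if design.n != data.n:
            raise ValueError("design and data disagree on the sample size")
        self.Xv = data.vectorized(center=True)
        self.F = design.F
        self.n = data.n
        self.G = self.F.T @ self.F                 # kr x kr
        self.C = self.Xv.T @ self.F                # pT x kr
        self.XtX = self.Xv.T @ self.Xv             # pT x pT
        self.rank_F = design.rank

    def resid_outer(self, W: np.ndarray) -> np.ndarray:
        """sum_i r_i r_i^T for residuals r_i = vec(X_i) - W f_i."""
        WC = W @ self.C.T
        return self.XtX - WC - WC.T + W @ self.G @ W.T


def fit_ols_unconstrained(data: MatrixDataset, design: CenteredDesign) -> np.ndarray:
    """OLS coefficients ``B = (F^T F)^-1 F^T X`` of shape (k*r) x (p*T)."""
    st = _Stats(data, design)
    return _ols_from_stats(st)


def _ols_from_stats(st: _Stats) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(st.G)
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular F^T F: reduce the number of basis functions (k*r) "
            "or provide more samples"
        )
    return linalg.cho_solve((c, low), st.C.T)


def fit_kpir_ls(
    data: MatrixDataset,
    design: CenteredDesign,
    dims: tuple[int, int] | None = None,
) -> KpirFit:
    """Least-squares K-PIR: VLP projection of the OLS coefficient matrix.

    ``dims=(k, r)`` partitions the coefficient; by default they are taken
    from the design.  The covariance estimate uses the residuals of the
    Kronecker-constrained mean with divisor ``n - rank(F)``.
    """
    k, r = dims if dims is not None else (design.k, design.r)
    T, p = data.T, data.p
    st = _Stats(data, design)
    B = _ols_from_stats(st)
    mean, _ = vlp_approx(B.T, (T, r, p, k))
    W = mean.product
    Delta = st.resid_outer(W) / (st.n - st.rank_F)
    Delta = (Delta + Delta.T) / 2.0
    return KpirFit(
        B_hat=B, mean=mean, Delta_hat=Delta, method="ls",
        dims=(T, r, p, k), Xbar=data.Xbar,
    )


def loglik(
    data: MatrixDataset,
    design: CenteredDesign,
    mean: KroneckerMean,
    Delta: np.ndarray,
) -> float:
    """Gaussian log-likelihood of the Kronecker inverse-regression model.

    Includes the ``-(n T p / 2) log 2 pi`` constant; ``Delta`` must be
    positive definite (evaluated through its Cholesky factorisation).
    """
    st = _Stats(data, design)
    return _loglik_from_stats(st, mean.product, Delta)


def _loglik_from_stats(st: _Stats, W: np.ndarray, Delta: np.ndarray) -> float:
    pT = Delta.shape[0]
    try:
        c, low = linalg.cho_factor(Delta)
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError("Delta must be positive definite")
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    M = st.resid_outer(W)
    quad = float(np.trace(linalg.cho_solve((c, low), M)))
    return -0.5 * st.n * pT * np.log(2.0 * np.pi) - 0.5 * st.n * logdet - 0.5 * quad


def update_delta_mle(
    data: MatrixDataset, design: CenteredDesign, mean: KroneckerMean
) -> np.ndarray:
    """Score-equation covariance update: (1/n) sum_i r_i r_i^T (divisor n)."""
    st = _Stats(data, design)
    D = st.resid_outer(mean.product) / st.n
    return (D + D.T) / 2.0


def _ridge_repair(Delta: np.ndarray, label: str) -> np.ndarray:
    """Make Delta numerically PD by adding a small multiple of the identity."""
    pT = Delta.shape[0]
    lam = 1e-8 * np.trace(Delta) / pT
    try:
        linalg.cho_factor(Delta)
        return Delta
    except linalg.LinAlgError:
        warnings.warn(f"{label}: covariance not positive definite; "
                      f"ridge {lam:.3e} added to the diagonal")
        w = linalg.eigvalsh(Delta)
        shift = max(lam, -w[0] + lam)
        return Delta + shift * np.eye(pT)


def fit_kpir_mle(
    data: MatrixDataset,
    design: CenteredDesign,
    dims: tuple[int, int] | None = None,
    tol1: float = 1e-6,
    tol2: float = 1e-6,
    max_iter: int = 100,
    ridge: float | None = None,
    inner_options: dict | None = None,
) -> KpirFit:
    """Maximum-likelihood K-PIR via block ascent.

    Starting at the least-squares solution, alternate (a) L-BFGS
    maximisation of the log-likelihood over the stacked free parameters
    ``(vec alpha, vec beta)`` at fixed ``Delta`` (analytic gradient) and
    (b) the closed-form ``Delta`` update, until the relative changes of
    both ``Delta`` and ``alpha (x) beta`` fall below ``tol1``/``tol2``.

    The likelihood needs ``Delta^{-1}``, so when ``n <= p*T`` the residual
    covariance is singular and fitting is refused unless an explicit
    ``ridge`` (added to the diagonal of every ``Delta`` iterate) is given.
    """
    k, r = dims if dims is not None else (design.k, design.r)
    T, p = data.T, data.p
    pT = p * T
    if data.n <= pT and ridge is None:
        raise ValueError(
            f"n = {data.n} <= pT = {pT}: Delta is singular; pass an explicit ridge"
        )
    st = _Stats(data, design)
    B = _ols_from_stats(st)
    mean, _ = vlp_approx(B.T, (T, r, p, k))
    alpha, beta = mean.alpha, mean.beta
    W = kron(alpha, beta)
    Delta = st.resid_outer(W) / (st.n - st.rank_F)
    Delta = (Delta + Delta.T) / 2.0
    if ridge is not None:
        Delta = Delta + ridge * np.eye(pT)
    Delta = _ridge_repair(Delta, "kpir-mle init")

    trace = [_loglik_from_stats(st, W, Delta)]
    opts = {"maxiter": 200, "ftol": 1e-10, "gtol": 1e-8}
    if inner_options:
        opts.update(inner_options)
    n_a = T * r
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Di = _pd_inverse(Delta)
        DiC = Di @ st.C

        def negloglik_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
            a = theta[:n_a].reshape(T, r)
            b = theta[n_a:].reshape(p, k)
            Wc = kron(a, b)
            DiW = Di @ Wc
            # 0.5 * tr(Di * resid_outer), dropping the alpha/beta-free term
            val = 0.5 * (
                -2.0 * float(np.sum(Wc * DiC))
                + float(np.sum((Wc.T @ DiW) * st.G))
            )
            S = DiW @ st.G - DiC            # d(val)/dW
            RS = nkp_rearrange(S, (T, r, p, k))
            ga = (RS @ b.ravel()).reshape(T, r)
            gb = (RS.T @ a.ravel()).reshape(p, k)
            return val, np.concatenate([ga.ravel(), gb.ravel()])

        theta0 = np.concatenate([alpha.ravel(), beta.ravel()])
        res = optimize.minimize(
            negloglik_grad, theta0, jac=True, method="L-BFGS-B", options=opts
        )
        if not res.success and res.status != 1:  # status 1 = maxiter reached
            warnings.warn(f"inner optimiser: {res.message}")
        alpha_new = res.x[:n_a].reshape(T, r)
        beta_new = res.x[n_a:].reshape(p, k)
        W_new = kron(alpha_new, beta_new)
        Delta_new = st.resid_outer(W_new) / st.n
        Delta_new = (Delta_new + Delta_new.T) / 2.0
        if ridge is not None:
            Delta_new = Delta_new + ridge * np.eye(pT)
        Delta_new = _ridge_repair(Delta_new, "kpir-mle")

        rel_d = np.linalg.norm(Delta_new - Delta) / max(np.linalg.norm(Delta), 1e-300)
        rel_w = np.linalg.norm(W_new - W) / max(np.linalg.norm(W), 1e-300)
        alpha, beta, W, Delta = alpha_new, beta_new, W_new, Delta_new
        trace.append(_loglik_from_stats(st, W, Delta))
        if rel_d < tol1 and rel_w < tol2:
            converged = True
            break
    if not converged:
        warnings.warn(f"kpir-mle did not converge in {max_iter} outer iterations")

    alpha, beta = apply_scale_convention(alpha, beta)
    return KpirFit(
        B_hat=B, mean=KroneckerMean(alpha, beta), Delta_hat=Delta, method="mle",
        dims=(T, r, p, k), Xbar=data.Xbar,
        loglik_trace=np.asarray(trace), n_iter=it, converged=converged,
    )


def _pd_inverse(S: np.ndarray) -> np.ndarray:
    c, low = linalg.cho_factor(S)
    inv = linalg.cho_solve((c, low), np.eye(S.shape[0]))
    return (inv + inv.T) / 2.0
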