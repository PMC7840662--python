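"""Synthetic data generators for the simulation studies.

Three designs are provided, mirroring the study conditions under which the
estimators are evaluated:

* a continuous-response design with a Fourier response basis and a
  Kronecker mean of controllable factor ranks,
* a binary two-group design with separable AR(1) predictor covariance and
  a monotone time-profile mean shift,
* a sparse continuous design with a quadratic response basis and a mean
  supported on two time points and one variable, with a noise scale knob.

Every generator returns the dataset together with the true parameters so
estimation error can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .dataset import MatrixDataset
from .design import build_binary, build_fourier, build_polynomial
from .kron import kron


@dataclass
class TruthParams:
    alpha: np.ndarray            # T x r
    beta: np.ndarray             # p x k
    Delta: np.ndarray            # pT x pT
    Gamma1: np.ndarray           # T x d1 orthonormal basis of span(alpha)
    Gamma2: np.ndarray           # p x d2 orthonormal basis of span(beta)

    @property
    def product(self) -> np.ndarray:
        return kron(self.alpha, self.beta)


def _padded_identity_pattern(d: int, r: int) -> np.ndarray:
    """d x r 0/1 coordinate matrix [I_d, 0] of rank d.

    This choice gives the mean factors exactly ``d`` unit entries, so the
    signal norm ``||alpha (x) beta||`` shrinks with the factor ranks --
    the scaling the published reduced-rank estimation errors follow.
    """
    g = np.zeros((d, r))
    g[np.arange(d), np.arange(d)] = 1.0
    return g


def _partial_identity(m: int, d: int) -> np.ndarray:
    G = np.zeros((m, d))
    G[:d, :d] = np.eye(d)
    return G


def ar1(dim: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix with entries rho^|i-j|."""
    idx = np.arange(dim)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class ContinuousSimConfig:
    n: int = 500
    p: int = 10
    T: int = 8
    k: int = 6
    r: int = 6
    d1: int = 6
    d2: int = 6
    delta: str | tuple[str, float] = "identity"  # "identity" or ("ar1", rho)
    noise_scale: float = 1.0
    seed: int | np.random.Generator = 0


def _delta_matrix(spec, pT: int) -> np.ndarray:
    """Positive definite error covariance with unit diagonal."""
    if spec == "identity":
        return np.eye(pT)
    if isinstance(spec, tuple) and spec[0] == "ar1":
        return ar1(pT, spec[1])
    if isinstance(spec, np.ndarray):
        if spec.shape != (pT, pT):
            raise ValueError("custom Delta has the wrong shape")
        if not np.allclose(np.diag(spec), 1.0):
            raise ValueError("custom Delta must have ones on the diagonal")
        return spec
    raise ValueError(f"unknown Delta spec {spec!r}")


def generate_continuous(cfg: ContinuousSimConfig) -> tuple[MatrixDataset, TruthParams]:
    """Continuous outcome: y ~ N(0,1), Fourier design, Kronecker mean.

    ``alpha = Gamma1 gamma1`` and ``beta = Gamma2 gamma2`` with
    partial-identity bases and padded-identity 0/1 coordinate patterns, so
    both factors have 0/1 entries and ranks ``d1``/``d2``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.d1 > min(cfg.T, cfg.r) or cfg.d2 > min(cfg.p, cfg.k):
        raise ValueError("requested factor ranks exceed matrix dimensions")
    G1 = _partial_identity(cfg.T, cfg.d1)
    G2 = _partial_identity(cfg.p, cfg.d2)
    alpha = G1 @ _padded_identity_pattern(cfg.d1, cfg.r)
    beta = G2 @ _padded_identity_pattern(cfg.d2, cfg.k)
    pT = cfg.p * cfg.T
    Delta = _delta_matrix(cfg.delta, pT)

    y = rng.standard_normal(cfg.n)
    design = build_fourier(y, cfg.k, cfg.r)
    W = kron(alpha, beta)                       # pT x kr
    eps = rng.standard_normal((cfg.n, pT))
    if not np.array_equal(Delta, np.eye(pT)):
        eps = eps @ np.linalg.cholesky(Delta).T
    Xv = design.F @ W.T + cfg.noise_scale * eps
    X = Xv.reshape(cfg.n, cfg.T, cfg.p).transpose(0, 2, 1)
    data = MatrixDataset(X, y)
    truth = TruthParams(alpha=alpha, beta=beta, Delta=cfg.noise_scale**2 * Delta,
                        Gamma1=G1, Gamma2=G2)
    return data, truth


@dataclass
class BinarySimConfig:
    n_per_group: int = 250
    p: int = 10
    T: int = 5
    rho_T: float = 0.3
    rho_p: float = 0.3
    shift_scale: float = 1.0     # multiplies the group-1 time profile
    seed: int | np.random.Generator = 0


def generate_binary(cfg: BinarySimConfig) -> tuple[MatrixDataset, TruthParams]:
    """Binary outcome: two Gaussian groups with a Kronecker mean shift.

    Group means are ``alpha_i (x) beta`` with ``alpha_0 = 0`` and
    ``alpha_1[t] = shift_scale / (T - t)`` (1-based: (T-k+1)^-1), so time
    points closer to the outcome carry more signal; ``beta`` weights all
    variables equally.  The marginal covariance is separable AR(1) x AR(1)
    and the within-group covariance follows from the variance decomposition
    ``Sigma_x = Delta + Cov(E(vec X | Y))``.
    """
    rng = np.random.default_rng(cfg.seed)
    T, p = cfg.T, cfg.p
    alpha1 = cfg.shift_scale / (T - np.arange(T)).astype(float)
    beta = np.full(p, p ** -0.5)
    t_vec = np.kron(alpha1, beta)               # pT mean difference
    Sigma_x = np.kron(ar1(T, cfg.rho_T), ar1(p, cfg.rho_p))
    Delta = Sigma_x - np.outer(t_vec, t_vec) / 4.0
    wmin = linalg.eigvalsh(Delta, subset_by_index=(0, 0))[0]
    if wmin <= 0:
        raise ValueError(
            "within-group covariance is not positive definite under this "
            "configuration; reduce shift_scale or the correlations"
        )
    n = 2 * cfg.n_per_group
    y = np.repeat([0, 1], cfg.n_per_group)
    L = np.linalg.cholesky(Delta)
    Xv = rng.standard_normal((n, p * T)) @ L.T
    Xv[y == 1] += t_vec
    X = Xv.reshape(n, T, p).transpose(0, 2, 1)
    data = MatrixDataset(X, y)
    truth = TruthParams(
        alpha=alpha1[:, None], beta=beta[:, None], Delta=Delta,
        Gamma1=(alpha1 / np.linalg.norm(alpha1))[:, None],
        Gamma2=beta[:, None],
    )
    return data, truth


@dataclass
class SparseSimConfig:
    n: int = 500
    p: int = 10
    T: int = 5
    scale: float = 1.0
    seed: int | np.random.Generator = 0


def generate_sparse(cfg: SparseSimConfig) -> tuple[MatrixDataset, TruthParams]:
    """Sparse continuous design: quadratic basis, support on 2 time points.

    ``alpha`` is T x 2 with unit entries at (1,1) and (2,2); ``beta`` is a
    length-p vector with a single unit entry.  The noise standard deviation
    is multiplied by ``scale`` (the noise-to-signal knob).
    """
    if cfg.scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(cfg.seed)
    T, p = cfg.T, cfg.p
    alpha = np.zeros((T, 2))
    alpha[0, 0] = alpha[1, 1] = 1.0
    beta = np.zeros((p, 1))
    beta[0, 0] = 1.0
    y = rng.standard_normal(cfg.n)
    design = build_polynomial(y, 2, k=1, r=2)
    W = kron(alpha, beta)
    Xv = design.F @ W.T + cfg.scale * rng.standard_normal((cfg.n, p * T))
    X = Xv.reshape(cfg.n, T, p).transpose(0, 2, 1)
    data = MatrixDataset(X, y)
    truth = TruthParams(
        alpha=alpha, beta=beta, Delta=cfg.scale**2 * np.eye(p * T),
        Gamma1=alpha.copy(), Gamma2=beta / np.linalg.norm(beta),
    )
    return data, truth
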