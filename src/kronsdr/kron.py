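"""Kronecker-product linear algebra primitives.

This module provides the three operations every estimator in the package is
built from:

* the Kronecker product itself,
* the nearest-Kronecker-product (NKP) approximation of Van Loan and
  Pitsianis, computed through the rearrangement trick and a rank-1 SVD,
* the Frobenius distance between orthogonal projections onto column spans,
  which is the subspace metric used throughout the simulation studies.

A matrix ``M`` of shape ``(T*p, r*k)`` is viewed as a ``T x r`` grid of
``p x k`` blocks, matching ``M = alpha (x) beta`` with ``alpha: T x r`` (the
time/column component) and ``beta: p x k`` (the variable/row component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


@dataclass
class KroneckerMean:
    """A Kronecker-factorised mean coefficient ``alpha (x) beta``.

    The factorisation is only identified up to the rescaling
    ``(c*alpha, beta/c)``.  The stored representative follows the
    ``beta_unit_frobenius`` convention: ``||beta||_F = 1`` and the
    largest-magnitude entry of ``beta`` is positive; ``alpha`` absorbs the
    scale and overall sign.
    """

    alpha: np.ndarray  # T x r
    beta: np.ndarray   # p x k
    scale_convention: str = "beta_unit_frobenius"

    @property
    def product(self) -> np.ndarray:
        """The ``(T*p) x (r*k)`` product ``alpha (x) beta``."""
        return kron(self.alpha, self.beta)

    def normalized(self) -> "KroneckerMean":
        """Return a copy rescaled to the ``beta_unit_frobenius`` convention."""
        a, b = apply_scale_convention(self.alpha, self.beta)
        return KroneckerMean(a, b)


@dataclass
class SubspaceBasis:
    """A full-column-rank basis of a linear subspace of R^m."""

    matrix: np.ndarray
    _orth: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        M = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if M.ndim != 2:
            raise ValueError("basis must be a 2-d matrix")
        self.matrix = M

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def orthonormal(self) -> np.ndarray:
        """An orthonormal basis of the same span (thin QR)."""
        if self._orth is None:
            M = self.matrix
            rank = np.linalg.matrix_rank(M)
            if rank < M.shape[1]:
                raise np.linalg.LinAlgError(
                    f"rank-deficient basis: rank {rank} < {M.shape[1]} columns"
                )
            q, _ = np.linalg.qr(M)
            self._orth = q
        return self._orth

    def projection(self) -> np.ndarray:
        """The orthogonal projection ``M (M^T M)^-1 M^T`` onto the span."""
        q = self.orthonormal()
        return q @ q.T


def kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Kronecker product ``a (x) b`` (thin wrapper, kept for a uniform API)."""
    return np.kron(np.asarray(a, dtype=float), np.asarray(b, dtype=float))


def nkp_rearrange(M: np.ndarray, dims: tuple[int, int, int, int]) -> np.ndarray:
    """Rearrangement R(M) underlying the nearest-Kronecker-product SVD.

    ``dims = (T, r, p, k)`` interprets ``M`` (shape ``(T*p, r*k)``) as a
    ``T x r`` grid of ``p x k`` blocks; row ``i*r + j`` of the result is the
    row-major vec of block ``(i, j)``.  Then ``R(alpha (x) beta) =
    vec(alpha) vec(beta)^T`` (both vecs row-major), so the best Kronecker
    approximation of ``M`` is the best rank-1 approximation of ``R(M)``.
    """
    T, r, p, k = dims
    M = np.asarray(M, dtype=float)
    if M.shape != (T * p, r * k):
        raise ValueError(
            f"matrix of shape {M.shape} does not match dims {(T, r, p, k)}: "
            f"expected {(T * p, r * k)}"
        )
    # (T, p, r, k) -> (T, r, p, k) -> (T*r, p*k)
    blocks = M.reshape(T, p, r, k).transpose(0, 2, 1, 3)
    return blocks.reshape(T * r, p * k)


def apply_scale_convention(
    alpha: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale ``(alpha, beta)`` so ``||beta||_F = 1`` with positive leading entry.

    The leading entry is the largest-magnitude entry of ``beta``; ``alpha``
    absorbs scale and sign so the product is unchanged.  Zero ``beta`` is
    returned unchanged.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    nb = np.linalg.norm(beta)
    if nb == 0.0:
        return alpha, beta
    s = nb * np.sign(beta.flat[np.argmax(np.abs(beta))])
    return alpha * s, beta / s


def vlp_approx(
    M: np.ndarray, dims: tuple[int, int, int, int]
) -> tuple[KroneckerMean, float]:
    """Nearest Kronecker product ``argmin ||M - alpha (x) beta||_F^2``.

    Computed by the Van Loan-Pitsianis rearrangement: the leading singular
    triplet ``(sigma, u, v)`` of :func:`nkp_rearrange` gives
    ``vec(alpha) = sqrt(sigma) u`` and ``vec(beta) = sqrt(sigma) v``
    (row-major vecs), after which the scale convention is applied.

    Returns the factor pair and the residual ``||M||_F^2 - sigma^2 >= 0``.
    """
    T, r, p, k = dims
    R = nkp_rearrange(M, dims)
    total = float(np.sum(R * R))
    if total == 0.0:
        # Degenerate all-zero input: zero factors, zero residual.
        return KroneckerMean(np.zeros((T, r)), np.zeros((p, k))), 0.0
    # Small dimensions throughout: full SVD is cheapest and most robust.
    u, s, vt = np.linalg.svd(R, full_matrices=False)
    sigma = s[0]
    alpha = np.sqrt(sigma) * u[:, 0].reshape(T, r)
    beta = np.sqrt(sigma) * vt[0].reshape(p, k)
    alpha, beta = apply_scale_convention(alpha, beta)
    residual = max(total - sigma**2, 0.0)
    return KroneckerMean(alpha, beta), residual


def projection_distance(A, B) -> float:
    """Frobenius distance ``||P_A - P_B||_F`` between span projections.

    Accepts :class:`SubspaceBasis` instances or plain full-column-rank
    matrices with equal row dimension.  The distance is invariant to
    right-multiplying either basis by an invertible matrix and is zero iff
    the spans coincide.
    """
    if not isinstance(A, SubspaceBasis):
        A = SubspaceBasis(np.asarray(A, dtype=float))
    if not isinstance(B, SubspaceBasis):
        B = SubspaceBasis(np.asarray(B, dtype=float))
    if A.matrix.shape[0] != B.matrix.shape[0]:
        raise ValueError("bases must share their row dimension")
    for name, basis in (("first", A), ("second", B)):
        try:
            basis.orthonormal()
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"{name} basis is rank deficient: {err}")
    return float(np.linalg.norm(A.projection() - B.projection()))


def factor_singular_bases(
    mean: KroneckerMean, d1: int, d2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Leading singular-vector bases of the two Kronecker factors.

    Returns the first ``d1`` left singular vectors of ``alpha`` and the
    first ``d2`` of ``beta`` (thin SVD), sign-fixed so each vector's
    largest-magnitude component is positive.  These span the estimated
    row/column mean subspaces used in the FMSDR basis.
    """
    g1 = _leading_left_singular(mean.alpha, d1)
    g2 = _leading_left_singular(mean.beta, d2)
    return g1, g2


def _leading_left_singular(M: np.ndarray, d: int) -> np.ndarray:
    u, s, _ = np.linalg.svd(np.asarray(M, dtype=float), full_matrices=False)
    if d > u.shape[1]:
        raise ValueError(f"cannot extract {d} singular vectors from shape {M.shape}")
    u = u[:, :d].copy()
    return fix_sign_columns(u)


def fix_sign_columns(M: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's largest-|entry| is positive."""
    M = np.array(M, dtype=float)
    for j in range(M.shape[1]):
        col = M[:, j]
        i = np.argmax(np.abs(col))
        if col[i] < 0:
            M[:, j] = -col
    return M


def nearest_semi_orthogonal(M: np.ndarray) -> np.ndarray:
    """Nearest semi-orthogonal matrix in Frobenius norm (polar factor)."""
    u, _, vt = np.linalg.svd(np.asarray(M, dtype=float), full_matrices=False)
    return u @ vt


def sym_inv_sqrt(S: np.ndarray, floor: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric square root and inverse square root via eigendecomposition.

    Eigenvalues are floored at ``floor * max(eigenvalue)`` before inversion;
    raises if the matrix is not positive definite up to that floor.
    """
    S = np.asarray(S, dtype=float)
    w, V = linalg.eigh((S + S.T) / 2.0)
    top = w[-1]
    if top <= 0:
        raise np.linalg.LinAlgError("matrix is not positive definite")
    w = np.maximum(w, floor * top)
    half = (V * np.sqrt(w)) @ V.T
    inv_half = (V / np.sqrt(w)) @ V.T
    return half, inv_half
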