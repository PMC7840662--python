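"""Response-function design matrices.

The inverse-regression model writes ``E(X | Y) - E(X)`` as a linear map of a
``k x r`` matrix of known functions ``f_Y`` with ``E(f_Y) = 0``.  At the
sample level only the column-centered ``n x (k*r)`` design of
``vec(f_{y_i})`` values enters any estimator, so this module builds that
matrix directly for the three families used in the studies: a Fourier basis
for continuous responses, the centered indicator for binary responses, and
low-degree polynomials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BasisSpec:
    family: str  # fourier | polynomial | indicator
    k: int = 1
    r: int = 1

    def __post_init__(self) -> None:
        if self.family not in ("fourier", "polynomial", "indicator"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.k < 1 or self.r < 1:
            raise ValueError("k and r must be positive")
        if self.family == "fourier" and (self.k * self.r) % 2 != 0:
            raise ValueError("fourier basis requires k*r even (cos/sin pairs)")


@dataclass
class CenteredDesign:
    """Column-centered design matrix F (n x k*r) with recorded column means."""

    F: np.ndarray
    column_means: np.ndarray
    k: int = 1
    r: int = 1

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def ncol(self) -> int:
        return self.F.shape[1]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.F))

    @property
    def full_rank(self) -> bool:
        return self.rank == min(self.F.shape)


def _center(raw: np.ndarray, k: int, r: int) -> CenteredDesign:
    means = raw.mean(axis=0)
    return CenteredDesign(raw - means, means, k=k, r=r)


def build_fourier(y: np.ndarray, k: int, r: int) -> CenteredDesign:
    """Fourier design: row i is (cos 2*pi*y_i, sin 2*pi*y_i, ..., cos 2*pi*s*y_i,
    sin 2*pi*s*y_i) with 2s = k*r, then column-centered."""
    y = np.asarray(y, dtype=float).ravel()
    kr = k * r
    if kr % 2 != 0:
        raise ValueError("fourier basis requires k*r even")
    if y.size <= kr:
        raise ValueError(f"need n > k*r = {kr} samples, got n = {y.size}")
    s = kr // 2
    freqs = 2.0 * np.pi * np.arange(1, s + 1)
    arg = np.outer(y, freqs)  # n x s
    raw = np.empty((y.size, kr))
    raw[:, 0::2] = np.cos(arg)
    raw[:, 1::2] = np.sin(arg)
    return _center(raw, k, r)


def build_binary(y: np.ndarray, positive_class: int = 1) -> CenteredDesign:
    """Centered two-group indicator design (k = r = 1).

    The single column is the centered indicator of ``positive_class``; with
    the default coding this is ``y - mean(y)``.  Published binary results
    that treat the Y=0 group as the positively-coded reference are obtained
    with ``positive_class=0``, which flips the column sign.
    """
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0, 1))):
        raise ValueError("binary design requires y in {0, 1}")
    if classes.size < 2:
        raise ValueError("both classes must be present in y")
    ind = (y == positive_class).astype(float)
    return _center(ind[:, None], 1, 1)


def build_polynomial(y: np.ndarray, degree: int, k: int = 1, r: int | None = None) -> CenteredDesign:
    """Polynomial design with columns (y, y^2, ..., y^degree), centered.

    A constant term contributes nothing after centering (it is absorbed by
    the overall mean), so it is never included.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    raw = np.column_stack([y**d for d in range(1, degree + 1)])
    if r is None:
        r = degree // k if degree % k == 0 else degree
    if k * r != degree:
        raise ValueError(f"(k, r) = {(k, r)} inconsistent with degree {degree}")
    return _center(raw, k, r)
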