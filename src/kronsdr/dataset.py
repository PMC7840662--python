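"""Container for samples of matrix-valued predictors with a scalar response.

Each sample is a ``p x T`` matrix (p variables/markers in rows, T time
points/channels in columns).  Vectorisation is always column-major over the
``p x T`` matrix, i.e. ``vec(X) = (X_.1^T, ..., X_.T^T)^T`` stacks the time
columns, so entry ``(variable j, time t)`` sits at vec index ``t*p + j``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MatrixDataset:
    X: np.ndarray  # n x p x T
    y: np.ndarray  # n
    centered: bool = False

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be an n x p x T array of matrices")
        y = np.asarray(self.y).ravel()
        if y.size != X.shape[0]:
            raise ValueError(
                f"{X.shape[0]} predictor matrices but {y.size} responses"
            )
        self.X = X
        self.y = y

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def T(self) -> int:
        return self.X.shape[2]

    @property
    def Xbar(self) -> np.ndarray:
        """Sample mean matrix (p x T)."""
        return self.X.mean(axis=0)

    def vectorized(self, center: bool = True) -> np.ndarray:
        """The n x pT data matrix with rows vec(X_i) (column-major vec).

        With ``center=True`` (the default for all estimators) the sample
        mean matrix is subtracted first.
        """
        X = self.X
        if center and not self.centered:
            X = X - self.Xbar
        # column-major vec of each p x T matrix: transpose to n x T x p then flatten
        return np.ascontiguousarray(X.transpose(0, 2, 1).reshape(self.n, -1))


def vec(M: np.ndarray) -> np.ndarray:
    """Column-major vec of a single p x T matrix."""
    return np.asarray(M, dtype=float).T.ravel()


def unvec(v: np.ndarray, p: int, T: int) -> np.ndarray:
    """Inverse of :func:`vec`: rebuild the p x T matrix."""
    return np.asarray(v, dtype=float).reshape(T, p).T
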