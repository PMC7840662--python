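"""Evaluation metrics for the simulation studies and classification.

Estimation quality is measured by relative Frobenius errors of the
Kronecker mean and the error covariance (E1, E2), Monte-Carlo variability
as the trace of the across-replicate empirical covariance of the
vectorised estimates (V1, V2), and subspace accuracy as Frobenius
distances between true and estimated span projections (Phi for the joint
mean subspace, phi1/phi2 for the time and variable factors).
Classification performance is summarised by the rank-based AUC with a
cross-validation driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .kron import kron, projection_distance
from .simulate import TruthParams


@dataclass
class RepFit:
    """Per-replicate estimate summary consumed by :func:`compute_metrics`."""

    mean_product: np.ndarray | None      # pT x kr estimate of alpha (x) beta
    Delta: np.ndarray | None
    Gamma1: np.ndarray | None
    Gamma2: np.ndarray | None


@dataclass
class SimMetrics:
    E1_mean: float
    E1_sd: float
    E2_mean: float
    E2_sd: float
    V1: float
    V2: float
    Phi: float
    phi1: float
    phi2: float
    n_reps: int

    def as_dict(self) -> dict[str, float]:
        return {
            "Mean E1": self.E1_mean, "SD E1": self.E1_sd,
            "Mean E2": self.E2_mean, "SD E2": self.E2_sd,
            "V1": self.V1, "V2": self.V2,
            "Phi": self.Phi, "phi1": self.phi1, "phi2": self.phi2,
        }


def _cov_trace(vectors: list[np.ndarray]) -> float:
    """Trace of the empirical (n-1 denominator) covariance across replicates."""
    V = np.stack(vectors)
    if V.shape[0] < 2:
        return float("nan")
    Vc = V - V.mean(axis=0)
    return float(np.sum(Vc * Vc) / (V.shape[0] - 1))


def compute_metrics(fits: list[RepFit], truth: TruthParams) -> SimMetrics:
    """Aggregate E1/E2 (mean and SD), V1/V2 and Phi/phi across replicates."""
    t_prod = truth.product
    t_norm = np.linalg.norm(t_prod)
    d_norm = np.linalg.norm(truth.Delta)
    e1, e2, phis, phi1s, phi2s = [], [], [], [], []
    prods, deltas = [], []
    for f in fits:
        if f.mean_product is not None:
            if f.mean_product.shape != t_prod.shape:
                raise ValueError("mean-product estimate does not match the truth shape")
            e1.append(np.linalg.norm(f.mean_product - t_prod) / t_norm)
            prods.append(f.mean_product.ravel())
        if f.Delta is not None:
            e2.append(np.linalg.norm(f.Delta - truth.Delta) / d_norm)
            deltas.append(f.Delta.ravel())
        if f.Gamma1 is not None and f.Gamma2 is not None:
            phis.append(
                projection_distance(kron(f.Gamma1, f.Gamma2),
                                    kron(truth.Gamma1, truth.Gamma2))
            )
            phi1s.append(projection_distance(f.Gamma1, truth.Gamma1))
            phi2s.append(projection_distance(f.Gamma2, truth.Gamma2))

    def _ms(x):
        if not x:
            return float("nan"), float("nan")
        x = np.asarray(x)
        return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else float("nan")

    e1m, e1s = _ms(e1)
    e2m, e2s = _ms(e2)
    return SimMetrics(
        E1_mean=e1m, E1_sd=e1s, E2_mean=e2m, E2_sd=e2s,
        V1=_cov_trace(prods) if prods else float("nan"),
        V2=_cov_trace(deltas) if deltas else float("nan"),
        Phi=float(np.mean(phis)) if phis else float("nan"),
        phi1=float(np.mean(phi1s)) if phi1s else float("nan"),
        phi2=float(np.mean(phi2s)) if phi2s else float("nan"),
        n_reps=len(fits),
    )


@dataclass
class AucResult:
    auc: float
    sd: float
    degenerate: bool = False


def evaluate_auc(scores: np.ndarray, labels: np.ndarray) -> AucResult:
    """Rank-based (Mann-Whitney) AUC with a Hanley-McNeil standard error.

    Constant scores carry no ranking information and return AUC 0.5 with
    the degenerate flag set.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        return AucResult(0.5, float("nan"), degenerate=True)
    auc = float(roc_auc_score(labels, scores))
    n1 = int(np.sum(labels == np.max(labels)))
    n0 = labels.size - n1
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n0 * n1)
    return AucResult(auc, float(np.sqrt(max(var, 0.0))))


def cross_validated_auc(data, fitter, folds: int | str = "loo", rng=None) -> AucResult:
    """Cross-validated AUC of a fitted scalar diagnostic score.

    ``fitter(train_data)`` must return a callable mapping a stack of p x T
    matrices to scalar scores.  Each fold's score orientation is fixed on
    the training data (group-1 training mean above group-0), so held-out
    scores are comparable across folds without touching test labels.
    ``folds="loo"`` gives leave-one-out; an integer gives k-fold with a
    deterministic interleaved assignment.
    """
    from .dataset import MatrixDataset

    n = data.n
    if folds == "loo":
        assignment = np.arange(n)
        n_folds = n
    else:
        n_folds = int(folds)
        assignment = np.arange(n) % n_folds
    held_scores = np.empty(n)
    for f in range(n_folds):
        test = assignment == f
        train = ~test
        sub = MatrixDataset(data.X[train], data.y[train])
        score_fn = fitter(sub)
        s_train = np.asarray(score_fn(sub.X), dtype=float).ravel()
        sign = 1.0
        mu1 = s_train[sub.y == 1].mean()
        mu0 = s_train[sub.y == 0].mean()
        if mu1 < mu0:
            sign = -1.0
        held_scores[test] = sign * np.asarray(score_fn(data.X[test]), dtype=float).ravel()
    return evaluate_auc(held_scores, data.y)
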