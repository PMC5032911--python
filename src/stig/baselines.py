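"""Reference combiners the spectral method is compared against.

Zero-calibration: majority vote (MV), an l1-regularized stacked regression
on classifier decisions (L1), a pooled-training MDRM (PMDRM), and the
omniscient best-single-subject transfer (MSS, diagnostic only). Calibration-
based: an accuracy-weighted ensemble (AWE) fitting simplex-constrained
least-squares weights on labeled calibration trials. The within-subject
calibration ceiling (CALIB) is plain MDRM fitting on the target's own
calibration split and is orchestrated by the evaluation harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .ensemble import PredictionMatrix
from .epochs import EpochSet
from .exceptions import DimensionMismatchError, OneClassError
from .mdrm import MDRMModel, fit_mdrm


@dataclass
class LinearCombiner:
    """A fitted linear rule over classifier decisions: sign(w . f + b)."""

    weights: np.ndarray
    intercept: float = 0.0
    method_tag: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("combiner weights must be finite")
        self.weights = w

    def predict(self, f) -> np.ndarray:
        """Labels from the weighted vote; an all-zero combiner falls back to
        majority vote with a warning. Ties resolve to -1."""
        vals = _values(f)
        if vals.shape[0] != self.weights.shape[0]:
            raise DimensionMismatchError("combiner/classifier count mismatch")
        if np.all(self.weights == 0):
            warnings.warn(
                "combiner has all-zero weights; falling back to majority vote",
                RuntimeWarning,
                stacklevel=2,
            )
            return majority_vote(f)
        scores = self.weights @ vals + self.intercept
        return np.where(scores > 0, 1, -1).astype(np.int8)


def _values(f) -> np.ndarray:
    return f.values if isinstance(f, PredictionMatrix) else np.asarray(f, dtype=float)


def majority_vote(f) -> np.ndarray:
    """Uniform vote over classifiers; ties resolve to -1."""
    sums = _values(f).sum(axis=0)
    return np.where(sums > 0, 1, -1).astype(np.int8)


def l1_ensemble_weights(
    source_predictions,
    source_labels: np.ndarray,
    lambda_grid: Sequence[float] = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
    cv_folds: int = 5,
    seed: int = 0,
) -> LinearCombiner:
    """Sparse linear stacking of classifier decisions.

    Solves ``argmin_w sum_j (y_j - w . F_j)^2 + lambda * ||w||_1`` with the
    penalty chosen by K-fold cross-validated squared error over
    ``lambda_grid``. ``source_predictions`` holds each classifier's decisions
    on pooled labeled source trials (entries of 0 mark abstentions, e.g. a
    classifier's own training subject under leave-one-subject-out stacking).
    Deterministic given ``seed``.
    """
    x = _values(source_predictions).T.astype(float)  # trials x classifiers
    y = np.asarray(source_labels, dtype=float)
    if y.shape != (x.shape[0],):
        raise DimensionMismatchError("labels must have one entry per trial")
    if np.unique(y).size < 2:
        raise OneClassError("l1 stacking requires labeled trials of both classes")
    n = x.shape[0]

    def fit_at(lam: float, xs, ys) -> np.ndarray:
        if lam == 0.0:
            w, *_ = np.linalg.lstsq(xs, ys, rcond=None)
            return w
        # sklearn's objective is (1/2n)||y-Xw||^2 + alpha||w||_1
        alpha = lam / (2 * xs.shape[0])
        model = Lasso(alpha=alpha, fit_intercept=False, max_iter=50_000)
        model.fit(xs, ys)
        return model.coef_

    grid = list(lambda_grid)
    if len(grid) > 1:
        kf = KFold(n_splits=min(cv_folds, n), shuffle=True, random_state=seed)
        cv_err = np.zeros(len(grid))
        for tr, te in kf.split(x):
            for gi, lam in enumerate(grid):
                w = fit_at(lam, x[tr], y[tr])
                resid = y[te] - x[te] @ w
                cv_err[gi] += float(resid @ resid)
        best = grid[int(np.argmin(cv_err))]
    else:
        best = grid[0]
    w = fit_at(best, x, y)
    return LinearCombiner(weights=w, method_tag=f"l1(lambda={best:g})")


def pooled_mdrm(sources: Sequence[EpochSet], tol: float = 1e-8, max_iter: int = 150) -> MDRMModel:
    """Single MDRM fitted on the concatenation of all source subjects'
    labeled trials (prototype = mean of all pooled target epochs)."""
    pooled = EpochSet.concatenate(list(sources))
    model = fit_mdrm(pooled, tol=tol, max_iter=max_iter)
    model.subject_id = "pooled"
    return model


def awe_weights(f_cal, y_cal: np.ndarray) -> LinearCombiner:
    """Accuracy-weighted ensemble: simplex-constrained least squares.

    Minimizes ``||y - F^T w||^2`` subject to ``w_i >= 0`` and ``sum w = 1``
    on labeled calibration trials. When every classifier gives identical
    decisions the optimum is non-unique and the tie is broken to uniform
    weights.
    """
    x = _values(f_cal).astype(float)  # m x n
    y = np.asarray(y_cal, dtype=float)
    m, n = x.shape
    if y.shape != (n,):
        raise DimensionMismatchError("labels must have one entry per trial")
    if np.unique(y).size < 2:
        raise OneClassError("AWE calibration requires both classes")
    if np.all(x == x[0]):
        return LinearCombiner(weights=np.full(m, 1.0 / m), method_tag="awe")

    gram = x @ x.T
    xy = x @ y

    def objective(w):
        r = w @ gram @ w - 2 * w @ xy + y @ y
        return r

    def gradient(w):
        return 2 * (gram @ w - xy)

    w0 = np.full(m, 1.0 / m)
    res = minimize(
        objective,
        w0,
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"AWE quadratic program failed: {res.message}")
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    return LinearCombiner(weights=w, method_tag="awe")


def unconstrained_awe_weights(f_cal, y_cal: np.ndarray) -> LinearCombiner:
    """Plain least-squares variant of AWE (no simplex constraint)."""
    x = _values(f_cal).T.astype(float)
    y = np.asarray(y_cal, dtype=float)
    w, *_ = np.linalg.lstsq(x, y, rcond=None)
    return LinearCombiner(weights=w, method_tag="awe-unconstrained")


def best_single_subject(f, y_true: np.ndarray) -> Tuple[int, float]:
    """Omniscient reference: the row with the highest balanced accuracy
    against ground truth (first occurrence wins ties). Diagnostic only."""
    from .evaluate import balanced_accuracy

    vals = _values(f)
    y_true = np.asarray(y_true)
    accs = np.array([balanced_accuracy(y_true, row) for row in vals])
    idx = int(np.argmax(accs))
    return idx, float(accs[idx])
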