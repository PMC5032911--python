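"""Spectral meta-learning: unsupervised combination of binary classifiers.

Given the +/-1 decisions of m conditionally independent classifiers on n
unlabeled trials, the population covariance of the decision vector is
approximately rank one, with principal eigenvector proportional to each
classifier's balanced-accuracy excess over chance, 2*pi_i - 1. The leading
eigenvector of the sample prediction covariance therefore weights
classifiers by their (unknown) accuracy without any labels.

Labels follow either the first-order rule sign(v . f) or, once per-
classifier sensitivity psi and specificity eta have been estimated from
provisional labels, the conditional-independence maximum-likelihood rule

    yhat = sign( sum_i f_i * alpha_i + beta_i ),
    alpha_i = log( psi_i eta_i / ((1-psi_i)(1-eta_i)) ),
    beta_i  = log( psi_i (1-psi_i) / (eta_i (1-eta_i)) ),

with a Dawid-Skene-style EM alternation between label and operating-point
estimates. The unsigned MLE sum serves as a per-trial confidence score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .epochs import EpochSet
from .exceptions import (
    DegenerateSpectrumError,
    DimensionMismatchError,
    OneClassError,
)
from .mdrm import MDRMModel, predict_epochs

# absolute floor for the operating-point clip
_CLIP_FLOOR = 1e-6


@dataclass
class PredictionMatrix:
    """m x n matrix of hard +/-1 ensemble decisions."""

    values: np.ndarray
    classifier_ids: Sequence[str] = None
    trial_ids: Sequence = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise DimensionMismatchError(
                f"prediction matrix must be m x n with m,n >= 1, got {v.shape}"
            )
        if not np.all(np.isin(v, (-1, 1))):
            raise ValueError("prediction matrix entries must be exactly -1 or +1")
        self.values = v.astype(np.int8)
        m, n = v.shape
        if self.classifier_ids is None:
            self.classifier_ids = tuple(f"clf{i}" for i in range(m))
        else:
            self.classifier_ids = tuple(str(c) for c in self.classifier_ids)
            if len(self.classifier_ids) != m:
                raise DimensionMismatchError("classifier_ids length must equal m")
        if self.trial_ids is None:
            self.trial_ids = tuple(range(n))
        else:
            self.trial_ids = tuple(self.trial_ids)
            if len(self.trial_ids) != n:
                raise DimensionMismatchError("trial_ids length must equal n")

    @property
    def n_classifiers(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]


@dataclass
class EnsembleWeights:
    """Spectral weights: unit principal eigenvector of the prediction
    covariance, its eigenvalue, and (optionally) per-classifier operating
    points."""

    v: np.ndarray
    eigenvalue: float
    psi_hat: Optional[np.ndarray] = None
    eta_hat: Optional[np.ndarray] = None

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float)
        if abs(np.linalg.norm(v) - 1.0) > 1e-12:
            raise ValueError("weight vector must have unit Euclidean norm")
        if v.sum() < 0:
            raise ValueError("weight vector violates the nonnegative-sum convention")
        self.v = v


def _values(f) -> np.ndarray:
    return f.values if isinstance(f, PredictionMatrix) else np.asarray(f)


def ensemble_predict(models: Sequence[MDRMModel], epochs: EpochSet) -> PredictionMatrix:
    """Hard decisions of every model on every epoch (rows = classifiers)."""
    bad = []
    for m in models:
        if tuple(m.channels) != tuple(epochs.channel_names) or m.fs != epochs.fs:
            bad.append(m.subject_id or "<unnamed>")
    if bad:
        raise DimensionMismatchError(
            f"models incompatible with the epoch geometry: {bad}"
        )
    rows = [predict_epochs(m, epochs)[0] for m in models]
    return PredictionMatrix(
        values=np.stack(rows),
        classifier_ids=[m.subject_id or f"clf{i}" for i, m in enumerate(models)],
        trial_ids=epochs.trial_ids,
    )


def prediction_covariance(f, weights: np.ndarray | None = None) -> np.ndarray:
    """Sample covariance of the ensemble decision vector across trials.

    ``weights`` (optional, positive, one per trial) implement an exponential
    forgetting window for streaming use; unweighted, this is the plain
    n-1-normalized covariance.
    """
    v = _values(f).astype(float)
    m, n = v.shape
    if n < 2:
        raise DimensionMismatchError("covariance requires at least 2 trials")
    if weights is None:
        return np.cov(v, ddof=1)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per trial")
    return np.cov(v, ddof=1, aweights=w)


def spectral_weights(q: np.ndarray) -> EnsembleWeights:
    """Leading unit eigenvector of the prediction covariance.

    The sign is resolved so the entries sum to a nonnegative value
    (ensemble members presumed better than chance). A leading eigenvalue
    that is not simple (gap below 1e-10 relative) is rejected, since the
    principal direction is then not identifiable.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise DimensionMismatchError("covariance must be a square matrix")
    w, vecs = np.linalg.eigh(0.5 * (q + q.T))
    lam = float(w[-1])
    if q.shape[0] >= 2:
        gap = lam - float(w[-2])
        if gap <= 1e-10 * max(abs(lam), 1e-300):
            raise DegenerateSpectrumError(
                "leading eigenvalue of the prediction covariance is not simple"
            )
    v = vecs[:, -1]
    s = v.sum()
    if s < 0:
        v = -v
    elif s == 0 and np.any(v != 0) and v[np.nonzero(v)[0][0]] < 0:
        # sum-zero edge case: fix the overall sign deterministically
        v = -v
    v = v / np.linalg.norm(v)
    return EnsembleWeights(v=v, eigenvalue=lam)


def sml_labels(f, w: EnsembleWeights | np.ndarray) -> np.ndarray:
    """First-order spectral labels: sign of the weighted vote, ties -> -1."""
    v = w.v if isinstance(w, EnsembleWeights) else np.asarray(w, dtype=float)
    vals = _values(f)
    if v.shape[0] != vals.shape[0]:
        raise DimensionMismatchError("weight length must equal the number of rows")
    scores = v @ vals
    return np.where(scores > 0, 1, -1).astype(np.int8)


def _laplace_clip(n_class: int, clip: float | None) -> float:
    if clip is not None:
        return float(clip)
    return max(1.0 / (2 * n_class + 2), _CLIP_FLOOR)


def estimate_operating_points(
    f, labels: np.ndarray, clip: float | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-classifier sensitivity and specificity against provisional labels.

    psi_i is the agreement rate on labels==+1 trials, eta_i on labels==-1
    trials; both are clipped into [clip, 1-clip]. When ``clip`` is None a
    Laplace-style per-class clip 1/(2 n_class + 2) is used (floored at 1e-6)
    so downstream log-likelihood ratios stay finite on small windows.
    """
    vals = _values(f)
    labels = np.asarray(labels)
    if labels.shape != (vals.shape[1],):
        raise DimensionMismatchError("labels must have one entry per trial")
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise OneClassError("operating points need provisional labels of both classes")
    clip_pos = _laplace_clip(int(pos.sum()), clip)
    clip_neg = _laplace_clip(int(neg.sum()), clip)
    psi = (vals[:, pos] == 1).mean(axis=1)
    eta = (vals[:, neg] == -1).mean(axis=1)
    psi = np.clip(psi, clip_pos, 1 - clip_pos)
    eta = np.clip(eta, clip_neg, 1 - clip_neg)
    return psi, eta


def _mle_terms(psi: np.ndarray, eta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    psi = np.asarray(psi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(psi <= 0) or np.any(psi >= 1) or np.any(eta <= 0) or np.any(eta >= 1):
        raise ValueError("psi and eta must lie strictly inside (0, 1)")
    alpha = np.log(psi * eta / ((1 - psi) * (1 - eta)))
    beta = np.log(psi * (1 - psi) / (eta * (1 - eta)))
    return alpha, beta


def mle_labels(
    f, psi: np.ndarray, eta: np.ndarray, literal: bool = False
) -> np.ndarray:
    """Maximum-likelihood labels under conditional independence.

    Default grouping applies the beta offset additively (the standard
    likelihood-ratio form); ``literal=True`` multiplies both log terms by
    the decision f_i, reproducing an alternative published rendering.
    Zero sums resolve to -1.
    """
    vals = _values(f).astype(float)
    alpha, beta = _mle_terms(psi, eta)
    if alpha.shape[0] != vals.shape[0]:
        raise DimensionMismatchError("psi/eta length must equal the number of rows")
    if literal:
        scores = (alpha + beta) @ vals
    else:
        scores = alpha @ vals + beta.sum()
    return np.where(scores > 0, 1, -1).astype(np.int8)


def trial_score(f_col: np.ndarray, psi: np.ndarray, eta: np.ndarray) -> float:
    """Unsigned MLE evidence for one trial: |sum_i f_i alpha_i + beta_i|."""
    f_col = np.asarray(f_col, dtype=float)
    alpha, beta = _mle_terms(psi, eta)
    if f_col.shape != alpha.shape:
        raise DimensionMismatchError("f_col length must match psi/eta")
    return float(abs(f_col @ alpha + beta.sum()))


class EMResult(NamedTuple):
    labels: np.ndarray
    psi_hat: np.ndarray
    eta_hat: np.ndarray
    iterations: int
    degenerate: bool = False


def em_refine(
    f,
    init_labels: np.ndarray,
    clip: float | None = None,
    max_iter: int = 50,
) -> EMResult:
    """Dawid-Skene-style EM refinement of ensemble labels.

    Alternates operating-point estimation against the current labels with
    MLE relabeling until the labels reach a fixed point or ``max_iter``
    relabelings have been applied. ``max_iter=0`` returns the initial labels
    with operating points estimated from them. If the labels collapse to a
    single class mid-iteration, the last valid state is returned with
    ``degenerate=True``.
    """
    vals = _values(f)
    labels = np.asarray(init_labels, dtype=np.int8)
    if labels.shape != (vals.shape[1],):
        raise DimensionMismatchError("init_labels must have one entry per trial")
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("init_labels must be +/-1")
    psi, eta = estimate_operating_points(f, labels, clip=clip)
    if max_iter == 0:
        return EMResult(labels, psi, eta, 0)
    for it in range(1, max_iter + 1):
        new_labels = mle_labels(f, psi, eta)
        if np.array_equal(new_labels, labels):
            return EMResult(labels, psi, eta, it)
        try:
            new_psi, new_eta = estimate_operating_points(f, new_labels, clip=clip)
        except OneClassError:
            warnings.warn(
                "EM labels collapsed to one class; returning last valid state",
                RuntimeWarning,
                stacklevel=2,
            )
            return EMResult(labels, psi, eta, it, degenerate=True)
        labels, psi, eta = new_labels, new_psi, new_eta
    return EMResult(labels, psi, eta, max_iter)
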