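"""Causal, trial-by-trial spectral transfer (STIG streaming engine).

Each incoming epoch is classified by every source-subject MDRM model,
producing one +/-1 column that is appended to the prediction history. While
the prediction covariance Q of the history is rank deficient (fewer
effective trials than ensemble members), labels fall back to a majority
vote — the cold start. Once Q reaches full numerical rank the engine
switches permanently to spectral mode: the principal eigenvector of Q
weights the ensemble, the current trial's label is the sign of the weighted
vote, and per-classifier operating points estimated from the provisional
labels yield an unsigned likelihood score for the trial.

Weight recomputation uses a full eigendecomposition per trial by default
(cheap at ensemble sizes of a few dozen). An O(m^2) rank-one
eigendecomposition update (secular-equation root finding with Loewner-type
re-orthogonalization) is provided as an optional path and agrees with the
full recomputation to high accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .ensemble import (
    EnsembleWeights,
    PredictionMatrix,
    estimate_operating_points,
    prediction_covariance,
    sml_labels,
    spectral_weights,
    trial_score,
    em_refine,
)
from .epochs import Epoch, EpochSet
from .exceptions import (
    ColdStartError,
    DegenerateSpectrumError,
    DimensionMismatchError,
    OneClassError,
)
from .mdrm import MDRMModel, predict_epochs

COLD_START = "cold_start"
SPECTRAL = "spectral"


@dataclass
class StreamConfig:
    """Tunables for the streaming engine.

    decay: exponential forgetting factor in (0, 1); None disables decay and
        uses the full growing window (the default).
    clip: operating-point clip; None selects the Laplace-style default.
    rank_tol: relative eigenvalue tolerance for the full-rank activation test.
    use_rank_one_update: compute weights by incremental eigendecomposition
        updates instead of a full eigendecomposition per trial.
    em_max_iter: iteration cap for retrospective EM relabeling.
    """

    decay: Optional[float] = None
    clip: Optional[float] = None
    rank_tol: float = 1e-10
    use_rank_one_update: bool = False
    em_max_iter: int = 50

    def __post_init__(self):
        if self.decay is not None and not (0.0 < self.decay < 1.0):
            raise ValueError("decay must lie in (0, 1) or be None")
        if self.decay is not None and self.use_rank_one_update:
            raise ValueError("rank-one updates require the undecayed window")


@dataclass
class StreamState:
    """Mutable state of one causal classification session."""

    models: Sequence[MDRMModel]
    config: StreamConfig
    columns: List[np.ndarray] = field(default_factory=list)
    emitted_labels: List[int] = field(default_factory=list)
    emitted_scores: List[float] = field(default_factory=list)
    emitted_modes: List[str] = field(default_factory=list)
    weight_log: List[Optional[np.ndarray]] = field(default_factory=list)
    mode: str = COLD_START
    switch_trial: Optional[int] = None
    current_weights: Optional[EnsembleWeights] = None
    _eig: Optional[tuple] = field(default=None, repr=False)

    @property
    def trial_count(self) -> int:
        return len(self.columns)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def history(self) -> PredictionMatrix:
        if not self.columns:
            raise ValueError("no trials processed yet")
        return PredictionMatrix(
            values=np.stack(self.columns, axis=1),
            classifier_ids=[m.subject_id or f"clf{i}" for i, m in enumerate(self.models)],
        )


def init_stream(
    models: Sequence[MDRMModel], config: StreamConfig | None = None
) -> StreamState:
    """Set up a session: at least two geometry-homogeneous models required."""
    models = list(models)
    if len(models) < 2:
        raise ValueError("streaming spectral transfer requires an ensemble (m >= 2)")
    ref = models[0]
    bad = [
        m.subject_id or f"model[{i}]"
        for i, m in enumerate(models)
        if tuple(m.channels) != tuple(ref.channels) or m.fs != ref.fs
    ]
    if bad:
        raise DimensionMismatchError(f"models with mismatched geometry: {bad}")
    return StreamState(models=models, config=config or StreamConfig())


def _majority(f: np.ndarray) -> int:
    return 1 if f.sum() > 0 else -1


def _decay_weights(n: int, decay: Optional[float]) -> Optional[np.ndarray]:
    if decay is None:
        return None
    return decay ** np.arange(n - 1, -1, -1, dtype=float)


def _rank_one_eig_update(
    d: np.ndarray, u: np.ndarray, rho: float, z: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of ``U diag(d) U^T + rho z z^T`` (rho > 0).

    ``d`` ascending. Near-duplicate eigenvalues are merged by Givens
    rotations so each cluster carries its z-mass on one coordinate; tiny
    z-components are deflated. Remaining roots of the secular equation
        1 + rho * sum z_i^2 / (d_i - lam) = 0
    are bracketed by eigenvalue interlacing and polished with brentq; the
    updated z is recomputed from the roots (Loewner formula), which keeps
    the new eigenvectors numerically orthogonal.
    """
    m = d.size
    zt = u.T @ z
    scale = max(float(np.abs(d).max(initial=0.0)), rho * float(zt @ zt), 1e-300)
    s = np.eye(m)

    # merge exact/near-duplicate eigenvalues: rotate z-mass onto one index
    dd = d.astype(float).copy()
    zz = zt.astype(float).copy()
    tol_d = 1e-14 * scale
    i = 0
    while i < m - 1:
        j = i
        while j < m - 1 and abs(dd[j + 1] - dd[j]) <= tol_d:
            j += 1
        if j > i:
            for k in range(i, j):
                # Givens rotation in the (k, j) plane zeroing zz[k]
                r = np.hypot(zz[k], zz[j])
                if r > 0:
                    c, sn = zz[j] / r, zz[k] / r
                    g = np.array([[c, -sn], [sn, c]])
                    s[:, [k, j]] = s[:, [k, j]] @ g.T
                    zz[k], zz[j] = 0.0, r
        i = j + 1

    defl_tol = 1e-13 * scale
    active = np.nonzero(rho * zz**2 > defl_tol)[0]
    new_d = dd.copy()
    s_new = s.copy()
    if active.size:
        da = dd[active]
        za = zz[active]
        p = active.size
        znorm2 = float(za @ za)

        def secular(lam):
            return 1.0 + rho * np.sum(za**2 / (da - lam))

        roots = np.empty(p)
        for k in range(p):
            lo = da[k]
            hi = da[k + 1] if k < p - 1 else da[p - 1] + rho * znorm2
            # nudge brackets off the poles until the signs straddle the root
            span = max(hi - lo, 1e-300)
            eps = 1e-15 * max(abs(lo), abs(hi), 1.0)
            a, b = lo + eps, hi - (eps if k < p - 1 else -eps)
            tries = 0
            while secular(a) >= 0 and tries < 60:
                eps *= 0.125
                a = lo + eps
                tries += 1
            eps_b = 1e-15 * max(abs(hi), 1.0)
            if k < p - 1:
                tries = 0
                while secular(b) <= 0 and tries < 60:
                    eps_b *= 0.125
                    b = hi - eps_b
                    tries += 1
            else:
                while secular(b) <= 0:
                    b = hi + span
                    span *= 2
            roots[k] = brentq(secular, a, b, xtol=1e-15 * max(abs(a), abs(b), 1.0),
                              rtol=8.9e-16, maxiter=200)

        # Loewner recomputation of z for numerically orthogonal eigenvectors
        za_hat = np.empty(p)
        for i_ in range(p):
            num = np.prod(roots - da[i_])
            den = rho * np.prod(np.delete(da, i_) - da[i_]) if p > 1 else rho
            val = num / den
            za_hat[i_] = np.sign(za[i_]) * np.sqrt(max(val, 0.0))

        vecs = np.empty((p, p))
        for k in range(p):
            w = za_hat / (da - roots[k])
            nw = np.linalg.norm(w)
            vecs[:, k] = w / nw if nw > 0 else np.eye(p)[:, k]

        new_d[active] = roots
        s_new[:, active] = s[:, active] @ vecs

    order = np.argsort(new_d)
    return new_d[order], (u @ s_new)[:, order]


class _EigTracker:
    """Running eigendecomposition of the prediction covariance."""

    def __init__(self, history: np.ndarray):
        self.n = history.shape[1]
        self.mean = history.mean(axis=1)
        q = np.cov(history.astype(float), ddof=1)
        self.d, self.u = np.linalg.eigh(q)

    def update(self, f: np.ndarray) -> None:
        n_new = self.n + 1
        delta = f.astype(float) - self.mean
        c = (self.n - 1) / self.n
        rho = 1.0 / n_new
        self.d, self.u = _rank_one_eig_update(c * self.d, self.u, rho, delta)
        self.mean = self.mean + delta / n_new
        self.n = n_new

    def leading(self) -> EnsembleWeights:
        v = self.u[:, -1]
        if v.sum() < 0:
            v = -v
        return EnsembleWeights(v=v / np.linalg.norm(v), eigenvalue=float(self.d[-1]))


def _predict_column(state: StreamState, x: Epoch) -> np.ndarray:
    single = EpochSet(
        signals=x.signal[None],
        labels=np.array([0], dtype=np.int8),
        fs=x.fs,
        subject_id=x.subject_id,
        channel_names=x.channel_names,
    )
    return np.array(
        [predict_epochs(m, single)[0][0] for m in state.models], dtype=np.int8
    )


def _full_rank(q: np.ndarray, rank_tol: float) -> bool:
    eig = np.linalg.eigvalsh(q)
    lead = eig[-1]
    if lead <= 0:
        return False
    return bool(np.all(eig > rank_tol * lead))


def process_trial(state: StreamState, x: Epoch) -> Tuple[int, float, StreamState]:
    """Classify one incoming epoch causally and update the session state.

    Returns ``(label, score, state)``. During cold start the label is the
    ensemble majority vote and the score the unsigned mean vote; in spectral
    mode the label is the weighted-vote sign under the current principal
    eigenvector and the score the unsigned MLE evidence under operating
    points estimated from the provisional spectral labels.
    """
    f = _predict_column(state, x)
    state.columns.append(f)
    n = state.trial_count
    hist = np.stack(state.columns, axis=1)
    cfg = state.config

    if state.mode == COLD_START and n >= 2:
        q = prediction_covariance(hist, weights=_decay_weights(n, cfg.decay))
        if _full_rank(q, cfg.rank_tol):
            state.mode = SPECTRAL
            state.switch_trial = n
            if cfg.use_rank_one_update:
                state._eig = _EigTracker(hist)

    if state.mode == COLD_START:
        label = _majority(f)
        score = float(abs(f.mean()))
        state.weight_log.append(None)
    else:
        if cfg.use_rank_one_update:
            if state._eig.n < n:
                state._eig.update(f)
            weights = state._eig.leading()
        else:
            q = prediction_covariance(hist, weights=_decay_weights(n, cfg.decay))
            try:
                weights = spectral_weights(q)
            except DegenerateSpectrumError:
                if state.current_weights is None:
                    raise
                warnings.warn(
                    "degenerate prediction covariance; reusing previous weights",
                    RuntimeWarning,
                    stacklevel=2,
                )
                weights = state.current_weights
        labels_all = sml_labels(hist, weights)
        label = int(labels_all[-1])
        try:
            psi, eta = estimate_operating_points(hist, labels_all, clip=cfg.clip)
            weights.psi_hat, weights.eta_hat = psi, eta
            score = trial_score(f, psi, eta)
        except OneClassError:
            # provisional labels one-sided: no operating points yet
            score = float(abs(f.mean()))
        state.current_weights = weights
        state.weight_log.append(weights.v.copy())

    state.emitted_labels.append(label)
    state.emitted_scores.append(score)
    state.emitted_modes.append(state.mode)
    return label, score, state


def relabel_history(state: StreamState) -> np.ndarray:
    """Retrospective EM relabeling of all accumulated trials.

    Refines the first-order spectral labels under the current weights via
    Dawid-Skene EM. Does not modify the emitted real-time label log. Only
    available once the stream has activated spectral mode.
    """
    if state.mode != SPECTRAL:
        raise ColdStartError("EM relabeling is unavailable during cold start")
    hist = state.history()
    init = sml_labels(hist, state.current_weights)
    result = em_refine(
        hist, init, clip=state.config.clip, max_iter=state.config.em_max_iter
    )
    return result.labels


def session_log(state: StreamState):
    """Per-trial session log as a DataFrame: trial, mode, label, score, and
    one weight column per ensemble member (NaN during cold start)."""
    import pandas as pd

    m = state.n_models
    ids = [mod.subject_id or f"clf{i}" for i, mod in enumerate(state.models)]
    rows = []
    for t in range(state.trial_count):
        w = state.weight_log[t]
        rows.append(
            {
                "trial_id": t,
                "mode": state.emitted_modes[t],
                "label": state.emitted_labels[t],
                "score": state.emitted_scores[t],
                **{
                    f"w_{ids[i]}": (np.nan if w is None else w[i]) for i in range(m)
                },
            }
        )
    return pd.DataFrame(rows)
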