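"""Epoch containers and information-geometric ERP features.

A trial is a channels-by-time EEG segment time-locked to a stimulus. The
feature map stacks a prototypical target response P (the mean of the labeled
target trials) on top of each trial X, giving the extended trial [P; X],
and takes its sample covariance across time — the extended sample covariance
matrix (ESCM). Covariance blocks between P and X capture how much of the
stereotyped target waveform is present in the trial, embedding temporal ERP
shape into a spatial-covariance feature that lives on the SPD cone.

This module assumes epochs are already windowed (e.g. [0, 1 s]
post-stimulus) and channel-selected; it performs no filtering, resampling,
or artifact rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DimensionMismatchError, MissingClassError
from .spd import SymmetricPositiveDefinite, _ensure_spd_stack

TARGET = 1
NONTARGET = -1
UNKNOWN = 0

# relative floor used to regularize rank-deficient ESCMs (scale-aware)
_ESCM_EPS_REL = 1e-10
_ESCM_EPS_ABS = 1e-12


def _default_channels(c: int) -> list[str]:
    return [f"ch{i}" for i in range(c)]


@dataclass(frozen=True)
class Epoch:
    """One trial: a C x N signal (microvolts) with label and provenance."""

    signal: np.ndarray
    label: int = UNKNOWN
    fs: float = 256.0
    subject_id: str = ""
    channel_names: Sequence[str] = ()

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[0] < 1 or sig.shape[1] < 2:
            raise DimensionMismatchError(
                f"epoch signal must be C x N with N >= 2, got shape {sig.shape}"
            )
        if not np.all(np.isfinite(sig)):
            raise ValueError("epoch signal contains non-finite samples")
        if self.label not in (TARGET, NONTARGET, UNKNOWN):
            raise ValueError(f"label must be -1, +1 or 0, got {self.label}")
        object.__setattr__(self, "signal", sig)
        names = list(self.channel_names) or _default_channels(sig.shape[0])
        if len(names) != sig.shape[0]:
            raise DimensionMismatchError("channel_names length must equal C")
        object.__setattr__(self, "channel_names", tuple(names))

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class EpochSet:
    """An ordered, shape-homogeneous collection of epochs.

    Stored densely as ``signals`` (n_trials, C, N) and ``labels`` (n_trials,)
    with entries in {-1, +1, 0(unknown)}; trial order is presentation order.
    """

    signals: np.ndarray
    labels: np.ndarray
    fs: float = 256.0
    subject_id: str = ""
    channel_names: Sequence[str] = ()
    trial_ids: Sequence = field(default=None)

    def __post_init__(self):
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim != 3:
            raise DimensionMismatchError(
                f"signals must be (n_trials, C, N), got shape {sig.shape}"
            )
        if sig.shape[2] < 2:
            raise DimensionMismatchError("epochs need at least 2 time samples")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signals contain non-finite samples")
        lab = np.asarray(self.labels, dtype=np.int8)
        if lab.shape != (sig.shape[0],):
            raise DimensionMismatchError("labels must have one entry per trial")
        if not np.all(np.isin(lab, (TARGET, NONTARGET, UNKNOWN))):
            raise ValueError("labels must be drawn from {-1, +1, 0}")
        self.signals = sig
        self.labels = lab
        names = list(self.channel_names) or _default_channels(sig.shape[1])
        if len(names) != sig.shape[1]:
            raise DimensionMismatchError("channel_names length must equal C")
        self.channel_names = tuple(names)
        if self.trial_ids is None:
            self.trial_ids = tuple(range(sig.shape[0]))
        else:
            self.trial_ids = tuple(self.trial_ids)
            if len(self.trial_ids) != sig.shape[0]:
                raise DimensionMismatchError("trial_ids length must equal n_trials")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.signals.shape[0]

    def __getitem__(self, i: int) -> Epoch:
        return Epoch(
            signal=self.signals[i],
            label=int(self.labels[i]),
            fs=self.fs,
            subject_id=self.subject_id,
            channel_names=self.channel_names,
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    # -- derived views -------------------------------------------------------
    def subset(self, index) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            signals=self.signals[index],
            labels=self.labels[index],
            fs=self.fs,
            subject_id=self.subject_id,
            channel_names=self.channel_names,
            trial_ids=tuple(np.asarray(self.trial_ids, dtype=object)[index]),
        )

    def select_channels(self, names: Iterable[str]) -> "EpochSet":
        """Subset channels by name (e.g. restrict to a standard ERP montage)."""
        names = list(names)
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise DimensionMismatchError(f"unknown channels: {missing}")
        idx = [self.channel_names.index(n) for n in names]
        return EpochSet(
            signals=self.signals[:, idx, :],
            labels=self.labels,
            fs=self.fs,
            subject_id=self.subject_id,
            channel_names=names,
            trial_ids=self.trial_ids,
        )

    @classmethod
    def from_epochs(cls, epochs: Sequence[Epoch]) -> "EpochSet":
        if not epochs:
            raise ValueError("cannot build an EpochSet from zero epochs")
        first = epochs[0]
        for e in epochs[1:]:
            if (
                e.signal.shape != first.signal.shape
                or e.fs != first.fs
                or e.channel_names != first.channel_names
            ):
                raise DimensionMismatchError("epochs are not shape-homogeneous")
        return cls(
            signals=np.stack([e.signal for e in epochs]),
            labels=np.array([e.label for e in epochs], dtype=np.int8),
            fs=first.fs,
            subject_id=first.subject_id,
            channel_names=first.channel_names,
        )

    @classmethod
    def concatenate(cls, sets: Sequence["EpochSet"]) -> "EpochSet":
        if not sets:
            raise ValueError("cannot concatenate zero EpochSets")
        first = sets[0]
        for s in sets[1:]:
            if (
                s.signals.shape[1:] != first.signals.shape[1:]
                or s.fs != first.fs
                or tuple(s.channel_names) != tuple(first.channel_names)
            ):
                raise DimensionMismatchError("EpochSets are not geometry-homogeneous")
        return cls(
            signals=np.concatenate([s.signals for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            fs=first.fs,
            subject_id="+".join(s.subject_id for s in sets if s.subject_id),
            channel_names=first.channel_names,
        )


@dataclass(frozen=True)
class Prototype:
    """Prototypical target response P: the mean labeled-target trial (C x N)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DimensionMismatchError("prototype must be a C x N matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("prototype contains non-finite values")
        object.__setattr__(self, "values", v)


def compute_prototype(train: EpochSet) -> Prototype:
    """Elementwise mean of the target-labeled epochs, P = E[X | y = +1]."""
    mask = train.labels == TARGET
    if not mask.any():
        raise MissingClassError("training set contains no target (+1) epochs")
    return Prototype(train.signals[mask].mean(axis=0))


def extend_trial(x, p: Prototype) -> np.ndarray:
    """Extended trial [P; X]: prototype stacked on top of the epoch (2C x N)."""
    sig = x.signal if isinstance(x, Epoch) else np.asarray(x, dtype=float)
    pv = p.values if isinstance(p, Prototype) else np.asarray(p, dtype=float)
    if sig.shape != pv.shape:
        raise DimensionMismatchError(
            f"epoch shape {sig.shape} does not match prototype shape {pv.shape}"
        )
    return np.vstack([pv, sig])


def _escm_eps(trace: np.ndarray, dim: int) -> np.ndarray:
    """Scale-aware regularization floor for ESCMs."""
    return np.where(trace > 0, _ESCM_EPS_REL * trace / dim, _ESCM_EPS_ABS)


def _escm_stack(ext: np.ndarray, eps: float | None = None) -> np.ndarray:
    """Sample covariance across time of a stack of extended trials.

    ``ext`` has shape (n, d, N); each trial is centered by its own column
    mean, normalized by N-1, then floored onto the SPD cone.
    """
    n_samp = ext.shape[-1]
    centered = ext - ext.mean(axis=-1, keepdims=True)
    cov = (centered @ np.swapaxes(centered, -1, -2)) / (n_samp - 1)
    cov = 0.5 * (cov + np.swapaxes(cov, -1, -2))
    if eps is None:
        eps_arr = _escm_eps(np.trace(cov, axis1=-2, axis2=-1), cov.shape[-1])
    else:
        eps_arr = np.full(cov.shape[0], float(eps))
    return _ensure_spd_stack(cov, eps_arr)


def escm(xt: np.ndarray, eps: float | None = None) -> SymmetricPositiveDefinite:
    """Extended sample covariance matrix of one extended trial (2C x N).

    Columns are centered by the trial's own mean column; normalization is by
    N - 1. The result is floored onto the SPD cone: by ``eps`` if given,
    otherwise by a relative floor of 1e-10 x trace/dim (absolute 1e-12 when
    the raw covariance is zero).
    """
    xt = np.asarray(xt, dtype=float)
    if xt.ndim != 2:
        raise DimensionMismatchError("extended trial must be a 2D matrix")
    if xt.shape[1] < 2:
        raise DimensionMismatchError("ESCM requires at least 2 time samples")
    if not np.all(np.isfinite(xt)):
        raise ValueError("extended trial contains non-finite values")
    return SymmetricPositiveDefinite(_escm_stack(xt[None], eps=eps)[0])
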