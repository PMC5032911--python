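"""Seeded synthetic-data generators.

Two harnesses make every stage of the pipeline testable without recorded
EEG:

1. A conditional-independence label-noise ensemble: m binary classifiers
   with prescribed sensitivity psi_i and specificity eta_i voting on trials
   with a given target prior — the generative model under which spectral
   meta-learning is derived.

2. A multi-subject rapid-serial-visual-presentation (RSVP) study: 1-second
   multichannel epochs at 256 Hz where rare target trials carry a
   P300-like positive deflection (a Gaussian time-course bump with a
   posterior-weighted scalp pattern, latency-jittered per trial) on top of
   temporally correlated AR(1) background noise. Between-subject scatter in
   amplitude, latency and topography makes subject-to-subject transfer
   heterogeneous, the premise of accuracy-weighted ensemble transfer.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.signal

from .ensemble import PredictionMatrix
from .epochs import EpochSet
from .exceptions import DimensionMismatchError


@dataclass(frozen=True)
class LabelNoiseSpec:
    """Conditionally independent binary ensemble with known operating points.

    psi/eta are per-classifier sensitivity/specificity in (0,1); ``prior``
    is P(y = +1).
    """

    m: int
    n: int
    psi: Sequence[float]
    eta: Sequence[float]
    prior: float = 0.1
    seed: int = 0

    def __post_init__(self):
        psi = np.asarray(self.psi, dtype=float)
        eta = np.asarray(self.eta, dtype=float)
        if psi.shape != (self.m,) or eta.shape != (self.m,):
            raise DimensionMismatchError("psi and eta must have length m")
        if np.any(psi <= 0) or np.any(psi >= 1) or np.any(eta <= 0) or np.any(eta >= 1):
            raise ValueError("psi and eta must lie strictly inside (0, 1)")
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie strictly inside (0, 1)")
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "eta", eta)


def uniform_operating_points(
    m: int, low: float = 0.55, high: float = 0.95, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw psi_i, eta_i ~ Uniform(low, high) independently."""
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=m), rng.uniform(low, high, size=m)


def simulate_label_noise_ensemble(
    spec: LabelNoiseSpec, max_retries: int = 100
) -> Tuple[PredictionMatrix, np.ndarray]:
    """Sample (predictions, true labels) from the label-noise model.

    y_j = +1 with probability ``prior`` i.i.d.; classifier i reproduces y_j
    with probability psi_i on targets and eta_i on non-targets, flipping it
    otherwise, independently across classifiers given the label. Draws are
    retried (up to ``max_retries``) if the sampled labels are one-class.
    """
    rng = np.random.default_rng(spec.seed)
    y = None
    for _ in range(max_retries):
        cand = np.where(rng.random(spec.n) < spec.prior, 1, -1).astype(np.int8)
        if np.unique(cand).size == 2 or spec.n == 1:
            y = cand
            break
    if y is None:
        raise RuntimeError(
            f"could not sample two-class labels in {max_retries} tries "
            f"(prior={spec.prior}, n={spec.n})"
        )
    p_correct = np.where(y == 1, spec.psi[:, None], spec.eta[:, None])
    agree = rng.random((spec.m, spec.n)) < p_correct
    f = np.where(agree, y, -y).astype(np.int8)
    return (
        PredictionMatrix(values=f, trial_ids=tuple(range(spec.n))),
        y,
    )


def _default_spatial_pattern(c: int) -> np.ndarray:
    """Smooth unit-norm scalp profile peaking over posterior channels."""
    idx = np.arange(c)
    w = np.exp(-0.5 * ((idx - 0.7 * (c - 1)) / (0.18 * c)) ** 2)
    return w / np.linalg.norm(w)


@dataclass(frozen=True)
class ERPStudySpec:
    """Multi-subject RSVP-style ERP study.

    Defaults emulate a 2 Hz RSVP target-detection session: 1 s epochs, 18
    channels at 256 Hz, a 1:9 target:background ratio, a ~16 uV P300-like
    bump at ~350 ms over ~10 uV AR(1) background noise, with moderate
    between-subject scatter in amplitude, latency and topography. The
    amplitude default is calibrated so that cross-subject transfer of
    per-subject classifiers lands in the regime reported for real RSVP
    studies (individual transfer balanced accuracies spread over roughly
    0.55-0.9, majority vote around 0.65-0.75) rather than at chance; raw
    unfiltered epochs are classified, so the template must carry the
    discriminative power a bandpass filter would otherwise concentrate.
    """

    subjects: int = 8
    trials_per_subject: int = 400
    channels: int = 18
    fs: float = 256.0
    epoch_length: float = 1.0
    target_ratio: float = 0.1
    # target template (within-subject)
    amplitude_uv: float = 16.0
    latency_ms: float = 350.0
    latency_jitter_ms: float = 30.0
    width_ms: float = 60.0
    spatial_pattern: Optional[Sequence[float]] = None
    # background noise
    ar_coeff: float = 0.95
    noise_sd_uv: float = 10.0
    # between-subject scatter
    amplitude_scatter: float = 0.25
    latency_scatter_ms: float = 40.0
    spatial_scatter: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_ratio < 1.0:
            raise ValueError("target_ratio must lie strictly inside (0, 1)")
        if self.noise_sd_uv <= 0 or self.width_ms <= 0:
            raise ValueError("variances and widths must be positive")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.channels < 1 or self.trials_per_subject < 2:
            raise ValueError("need at least 1 channel and 2 trials per subject")
        if self.spatial_pattern is not None:
            sp = np.asarray(self.spatial_pattern, dtype=float)
            if sp.shape != (self.channels,):
                raise DimensionMismatchError("spatial_pattern must have C entries")
            object.__setattr__(self, "spatial_pattern", sp / np.linalg.norm(sp))

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_length))


def _ar1_noise(rng: np.random.Generator, shape: tuple, a: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with marginal SD ``sd``."""
    burn = 100
    n = shape[-1]
    white = rng.standard_normal(shape[:-1] + (n + burn,))
    innov_sd = sd * np.sqrt(1.0 - a * a) if a > 0 else sd
    x = scipy.signal.lfilter([1.0], [1.0, -a], innov_sd * white, axis=-1)
    return x[..., burn:]


def _subject_params(spec: ERPStudySpec, rng: np.random.Generator) -> dict:
    base = (
        np.asarray(spec.spatial_pattern)
        if spec.spatial_pattern is not None
        else _default_spatial_pattern(spec.channels)
    )
    amp = spec.amplitude_uv * np.exp(spec.amplitude_scatter * rng.standard_normal())
    lat = spec.latency_ms + spec.latency_scatter_ms * rng.standard_normal()
    spatial = base + spec.spatial_scatter * rng.standard_normal(spec.channels) / np.sqrt(
        spec.channels
    )
    nrm = np.linalg.norm(spatial)
    spatial = spatial / nrm if nrm > 0 else base
    return {"amplitude": amp, "latency_ms": lat, "spatial": spatial}


def simulate_subject(
    spec: ERPStudySpec, subject_index: int = 0, seed: Optional[int] = None
) -> EpochSet:
    """One subject's labeled epoch stream.

    Subject-level template parameters are drawn once from the between-
    subject distributions; target counts are stratified (exactly
    round(n * ratio)) and trial order is shuffled. Deterministic per
    (seed, subject_index).
    """
    root = spec.seed if seed is None else seed
    rng = np.random.default_rng([int(root) % (2**31), int(subject_index)])
    params = _subject_params(spec, rng)
    n = spec.trials_per_subject
    c = spec.channels
    n_samp = spec.n_samples

    n_target = int(round(n * spec.target_ratio))
    labels = np.full(n, -1, dtype=np.int8)
    labels[:n_target] = 1
    rng.shuffle(labels)

    signals = _ar1_noise(rng, (n, c, n_samp), spec.ar_coeff, spec.noise_sd_uv)

    t_ms = np.arange(n_samp) / spec.fs * 1000.0
    tgt = np.nonzero(labels == 1)[0]
    if tgt.size:
        jitter = spec.latency_jitter_ms * rng.standard_normal(tgt.size)
        centers = params["latency_ms"] + jitter
        bumps = np.exp(
            -0.5 * ((t_ms[None, :] - centers[:, None]) / spec.width_ms) ** 2
        )
        # amplitude is the peak deflection on the strongest channel
        peak = np.abs(params["spatial"]).max()
        gain = params["amplitude"] / peak if peak > 0 else params["amplitude"]
        signals[tgt] += gain * params["spatial"][None, :, None] * bumps[:, None, :]

    return EpochSet(
        signals=signals,
        labels=labels,
        fs=spec.fs,
        subject_id=f"sim{subject_index:02d}",
        channel_names=[f"ch{i}" for i in range(c)],
    )


def simulate_study(spec: ERPStudySpec, seed: Optional[int] = None) -> List[EpochSet]:
    """S independent subjects drawn from shared hyper-distributions."""
    if spec.subjects < 2:
        raise ValueError("a study needs at least 2 subjects")
    return [
        simulate_subject(spec, subject_index=i, seed=seed)
        for i in range(spec.subjects)
    ]
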