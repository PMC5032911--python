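"""Shared fixtures: random SPD matrices and a small, fast synthetic study.

The study fixture uses a deliberately tiny geometry (4 channels, 64 Hz,
0.25 s epochs -> 8-dimensional ESCMs) so that model fitting stays in the
tens of milliseconds and integration tests remain cheap.
"""

import dataclasses

import numpy as np
import pytest

from stig.evaluate import fit_study_models
from stig.simulate import ERPStudySpec, simulate_study


def random_spd(rng: np.random.Generator, dim: int, cond: float = 50.0) -> np.ndarray:
    """Random SPD matrix with eigenvalues log-spread up to ``cond``."""
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    eigs = np.exp(rng.uniform(0.0, np.log(cond), size=dim))
    return (q * eigs) @ q.T


@pytest.fixture(scope="session")
def tiny_spec() -> ERPStudySpec:
    return ERPStudySpec(
        subjects=4,
        trials_per_subject=60,
        channels=4,
        fs=64.0,
        epoch_length=0.25,
        target_ratio=0.2,
        amplitude_uv=25.0,
        noise_sd_uv=10.0,
        # the 0.25 s window requires an early deflection; the defaults put
        # the bump at 350 ms, outside this epoch
        latency_ms=120.0,
        latency_jitter_ms=15.0,
        latency_scatter_ms=20.0,
        width_ms=40.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_spec):
    return simulate_study(tiny_spec)


@pytest.fixture(scope="session")
def tiny_models(tiny_study):
    return fit_study_models(tiny_study)


@pytest.fixture(scope="session")
def tiny_spec_factory(tiny_spec):
    """Variants of the tiny spec with fields overridden."""

    def make(**overrides) -> ERPStudySpec:
        return dataclasses.replace(tiny_spec, **overrides)

    return make
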