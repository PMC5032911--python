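"""Numerics on the manifold of symmetric positive definite (SPD) matrices.

Extended-trial covariance matrices of ERP epochs live on the open cone of
SPD matrices. Distances use the affine-invariant Riemannian metric (AIRM),

    delta(A, B) = || log(A^{-1/2} B A^{-1/2}) ||_F,

which is invariant under any invertible linear transform W: delta(W A W^T,
W B W^T) = delta(A, B). Class centroids are Frechet (geometric) means under
this metric, computed by a fixed-point Karcher flow.

All public functions accept either a raw ndarray or a
:class:`SymmetricPositiveDefinite` wrapper; stacked (batched) private
helpers operate on ``(..., d, d)`` arrays and back the hot paths of the
classifier modules.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from .exceptions import (
    ConvergenceError,
    DimensionMismatchError,
    NotSPDError,
    NotSymmetricError,
)

# Eigenvalue floor applied before matrix logarithms; keeps log finite on
# nearly-singular inputs without perturbing well-conditioned ones.
_LOG_EIG_FLOOR = 1e-12

# Relative asymmetry below which inputs are silently symmetrized.
_SYM_RTOL = 1e-8


def _as_matrix(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def _check_symmetric(m: np.ndarray, rtol: float = _SYM_RTOL) -> np.ndarray:
    """Symmetrize ``m`` if its asymmetry is within tolerance, else raise."""
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DimensionMismatchError(f"expected a square matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise NotSPDError("matrix contains non-finite entries")
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > rtol * scale:
        raise NotSymmetricError("matrix is not symmetric within tolerance")
    return 0.5 * (m + m.T)


class SymmetricPositiveDefinite:
    """A validated SPD matrix.

    Construction symmetrizes inputs whose asymmetry is within relative
    tolerance and rejects matrices with a non-positive spectrum.
    """

    __slots__ = ("values",)

    def __init__(self, values):
        m = _check_symmetric(_as_matrix(values))
        if np.linalg.eigvalsh(m)[0] <= 0.0:
            raise NotSPDError("matrix has a non-positive eigenvalue")
        m.setflags(write=False)
        object.__setattr__(self, "values", m)

    def __setattr__(self, name, value):
        raise AttributeError("SymmetricPositiveDefinite is immutable")

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"SymmetricPositiveDefinite(dim={self.dim})"


def _eigh_stack(mats: np.ndarray):
    return np.linalg.eigh(mats)


def _sym_apply(mats: np.ndarray, fn) -> np.ndarray:
    """Apply a scalar function to the spectrum of a stack of symmetric
    matrices: V diag(fn(w)) V^T."""
    w, v = _eigh_stack(mats)
    return (v * fn(w)[..., None, :]) @ np.swapaxes(v, -1, -2)


def _logm(mats: np.ndarray) -> np.ndarray:
    return _sym_apply(mats, lambda w: np.log(np.clip(w, _LOG_EIG_FLOOR, None)))


def _expm(mats: np.ndarray) -> np.ndarray:
    return _sym_apply(mats, np.exp)


def _sqrtm(mats: np.ndarray) -> np.ndarray:
    return _sym_apply(mats, lambda w: np.sqrt(np.clip(w, 0.0, None)))


def _invsqrtm(mats: np.ndarray) -> np.ndarray:
    return _sym_apply(mats, lambda w: 1.0 / np.sqrt(np.clip(w, _LOG_EIG_FLOOR, None)))


def _validate_spd_pair(a, b):
    a = _check_symmetric(_as_matrix(a))
    b = _check_symmetric(_as_matrix(b))
    if a.shape != b.shape:
        raise DimensionMismatchError(
            f"dimension mismatch: {a.shape} vs {b.shape}"
        )
    for m in (a, b):
        if np.linalg.eigvalsh(m)[0] <= 0.0:
            raise NotSPDError("input matrix is not positive definite")
    return a, b


def airm_distance(a, b) -> float:
    """AIRM geodesic distance between two SPD matrices.

    Computed from the generalized eigenvalues of (b, a): the distance is the
    Euclidean norm of their logs, which equals ||log(a^{-1/2} b a^{-1/2})||_F.
    Symmetric in its arguments; zero iff a == b.
    """
    a, b = _validate_spd_pair(a, b)
    w = scipy.linalg.eigvalsh(b, a)
    w = np.clip(w, _LOG_EIG_FLOOR, None)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def _dists_to_ref(mats: np.ndarray, ref_invsqrt: np.ndarray) -> np.ndarray:
    """AIRM distances from a stack of SPD matrices to one reference, given the
    reference's inverse square root (hot path: stacked eigvalsh)."""
    whitened = ref_invsqrt @ mats @ ref_invsqrt
    w = np.linalg.eigvalsh(whitened)
    w = np.clip(w, _LOG_EIG_FLOOR, None)
    return np.sqrt((np.log(w) ** 2).sum(axis=-1))


def _stack(mats: Iterable) -> np.ndarray:
    arr = np.stack([_as_matrix(m) for m in mats])
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise DimensionMismatchError("inputs must be square matrices of equal size")
    return arr


def frechet_mean(
    mats: Sequence,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> SymmetricPositiveDefinite:
    """Frechet (geometric) mean of SPD matrices under the AIRM.

    Fixed-point Karcher flow: map the inputs through the log at the current
    iterate, average in the tangent space, and exponentiate back (step size
    1.0), starting from the arithmetic mean. Returns when the Riemannian
    gradient ``|| sum_i log(M^{-1/2} S_i M^{-1/2}) ||_F`` is at most ``tol``.

    Raises
    ------
    ConvergenceError
        If the gradient condition is not met within ``max_iter`` iterations;
        the exception carries the last iterate.
    """
    mats = list(mats)
    if len(mats) == 0:
        raise ValueError("frechet_mean requires at least one matrix")
    if tol <= 0:
        raise ValueError("tol must be positive")
    arr = _stack(mats)
    n = arr.shape[0]
    if n == 1:
        return SymmetricPositiveDefinite(arr[0])
    m = arr.mean(axis=0)
    grad_norm = np.inf
    for _ in range(max_iter):
        w, v = np.linalg.eigh(m)
        w = np.clip(w, _LOG_EIG_FLOOR, None)
        m_isqrt = (v / np.sqrt(w)) @ v.T
        m_sqrt = (v * np.sqrt(w)) @ v.T
        tangent = _logm(m_isqrt @ arr @ m_isqrt)
        mean_tangent = tangent.mean(axis=0)
        grad_norm = n * float(np.linalg.norm(mean_tangent))
        if grad_norm <= tol:
            return SymmetricPositiveDefinite(m)
        m = m_sqrt @ _expm(mean_tangent) @ m_sqrt
        m = 0.5 * (m + m.T)
    # one last gradient check at the updated iterate
    m_isqrt = _invsqrtm(m)
    tangent = _logm(m_isqrt @ arr @ m_isqrt)
    grad_norm = n * float(np.linalg.norm(tangent.mean(axis=0)))
    if grad_norm <= tol:
        return SymmetricPositiveDefinite(m)
    raise ConvergenceError(
        f"Frechet mean did not converge in {max_iter} iterations "
        f"(gradient norm {grad_norm:.3e} > tol {tol:.3e})",
        last_iterate=m,
        gradient_norm=grad_norm,
    )


def ensure_spd(m, eps: float) -> SymmetricPositiveDefinite:
    """Shift a symmetric matrix onto the SPD cone.

    Returns ``m + c*I`` with the smallest ``c >= 0`` such that the minimum
    eigenvalue is at least ``eps``; ``m`` is returned unchanged when it
    already satisfies the bound.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    m = _check_symmetric(_as_matrix(m))
    min_eig = float(np.linalg.eigvalsh(m)[0])
    if min_eig >= eps:
        return SymmetricPositiveDefinite(m)
    c = eps - min_eig
    return SymmetricPositiveDefinite(m + c * np.eye(m.shape[0]))


def _ensure_spd_stack(mats: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Vectorized ensure_spd on a stack; ``eps`` broadcasts over the stack."""
    min_eig = np.linalg.eigvalsh(mats)[..., 0]
    c = np.clip(eps - min_eig, 0.0, None)
    out = mats.copy()
    idx = np.nonzero(c > 0)[0]
    if idx.size:
        d = mats.shape[-1]
        out[idx] += c[idx, None, None] * np.eye(d)
    return out
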