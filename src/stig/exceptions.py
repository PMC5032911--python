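"""Error signals raised across the package.

Most inherit :class:`ValueError` so callers that do not care about the
fine-grained taxonomy can catch the standard type.
"""


class StigError(Exception):
    """Base class for all package-specific errors."""


class DimensionMismatchError(StigError, ValueError):
    """Operands have incompatible shapes, channel sets, or sampling rates."""


class NotSymmetricError(StigError, ValueError):
    """A matrix expected to be symmetric is not, beyond tolerance."""


class NotSPDError(StigError, ValueError):
    """A matrix expected to be symmetric positive definite has a
    non-positive eigenvalue."""


class ConvergenceError(StigError, RuntimeError):
    """An iterative solver failed to reach its tolerance.

    Carries the last iterate so callers may inspect or accept it.
    """

    def __init__(self, message, last_iterate=None, gradient_norm=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.gradient_norm = gradient_norm


class MissingClassError(StigError, ValueError):
    """A labeled set lacks one of the two classes required for fitting."""


class OneClassError(StigError, ValueError):
    """Labels contain a single class where both are required (e.g. for
    sensitivity/specificity or balanced accuracy)."""


class DegenerateSpectrumError(StigError, ValueError):
    """The leading eigenvalue of the prediction covariance is not simple,
    so the principal eigenvector is not identifiable."""


class ColdStartError(StigError, RuntimeError):
    """A spectral-mode operation was requested while the stream is still in
    its majority-vote cold start."""
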