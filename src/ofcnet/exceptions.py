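"""Exception hierarchy for ofcnet.

All package errors derive from :class:`OfcnetError` so callers can catch
one base class. Errors carry enough state to diagnose the failure (e.g.
the offending eigenvalue, or the best-so-far interaction matrix on
non-convergence).
"""


class OfcnetError(Exception):
    """Base class for all ofcnet errors."""


class FormatError(OfcnetError):
    """Input file could not be parsed in the expected format."""


class InsufficientEnsembleError(OfcnetError):
    """Fewer than two usable models in a structural ensemble."""


class AlignmentError(OfcnetError):
    """Models of an ensemble share no common residue core."""


class DegenerateGeometryError(OfcnetError):
    """Geometry too degenerate (collinear, <3 points) for superposition."""


class NotSuperposedError(OfcnetError):
    """Operation requires a superposed ensemble."""


class SingularMatrixError(OfcnetError):
    """Matrix is singular (or indefinite) where an inverse is required."""

    def __init__(self, msg: str, eigenvalue: float | None = None):
        super().__init__(msg)
        self.eigenvalue = eigenvalue


class ConstraintError(OfcnetError):
    """Covariance constraints are inconsistent (e.g. nonpositive MSF)."""


class ConvergenceError(OfcnetError):
    """Optimizer exhausted its step budget.

    Attributes
    ----------
    best : InteractionMatrix
        Best iterate found before the budget ran out.
    residual : float
        Scaled constraint residual of ``best``.
    """

    def __init__(self, msg: str, best=None, residual: float | None = None):
        super().__init__(msg)
        self.best = best
        self.residual = residual


class NormalizationError(OfcnetError):
    """Force-constant table has no nonzero entries to normalize by."""


class AnnotationError(OfcnetError):
    """Secondary-structure / H-bond annotation unavailable or inconsistent."""


class InsufficientDataError(OfcnetError):
    """Too few observations for a statistic to be defined."""


class FitError(OfcnetError):
    """Curve fit undefined (e.g. constant input curve)."""
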