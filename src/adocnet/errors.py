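"""Exception types shared across the package."""


class AdocnetError(ValueError):
    """Base class for all validation and estimation failures."""


class ValidationError(AdocnetError):
    """Malformed inputs: unknown ids, bad codes, inconsistent shapes."""


class SeparationError(AdocnetError):
    """Pseudolikelihood logistic fit is separated or collinear.

    Carries the name of the offending model term in ``term``.
    """

    def __init__(self, message: str, term: str | None = None):
        super().__init__(message)
        self.term = term


class BoundaryError(AdocnetError):
    """Observed statistic on the boundary of its convex hull (MLE at infinity)."""

    def __init__(self, message: str, term: str | None = None):
        super().__init__(message)
        self.term = term


class DegeneracyError(AdocnetError):
    """Model-based simulation drifted to a degenerate region of graph space."""

    def __init__(self, message: str, term: str | None = None, diagnostics=None):
        super().__init__(message)
        self.term = term
        self.diagnostics = diagnostics or {}


class NonConvergenceError(AdocnetError):
    """An iterative solver exhausted its iteration budget."""
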