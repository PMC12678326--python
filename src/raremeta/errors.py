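"""Exception hierarchy shared across the package."""


class RareMetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RareMetaError):
    """Input CSV does not match the documented schema."""


class ValidationError(RareMetaError):
    """A study record violates a data invariant."""


class InconsistencyError(RareMetaError):
    """A derived event count cannot be reconciled with the printed percentage."""


class InsufficientStudiesError(RareMetaError):
    """An operation needs more studies than the input provides."""


class EmptySelectionError(RareMetaError):
    """A subgroup selector retained no studies."""


class NonConvergenceError(RareMetaError):
    """MCMC diagnostics failed the convergence contract.

    Carries the offending diagnostics in ``self.diagnostics``.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class BoundaryError(RareMetaError):
    """A fit is not identifiable (e.g. all event counts are zero)."""


class FitError(RareMetaError):
    """Optimizer failed to converge from every starting point."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class ConsistencyError(RareMetaError):
    """Two inputs that must describe the same studies do not."""
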