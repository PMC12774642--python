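"""Exception hierarchy shared across the package."""


class QuadbindError(Exception):
    """Base class for all package-specific errors."""


class DomainError(QuadbindError, ValueError):
    """An input violates a precondition (negative concentration, K <= 0, ...)."""


class SchemaError(QuadbindError, ValueError):
    """A CSV or config file does not match the documented schema."""


class FitError(QuadbindError, RuntimeError):
    """A nonlinear fit could not be carried out (too few points, no convergence)."""


class TransitionOutOfRangeError(FitError):
    """A melting transition is not visible inside the measured temperature range."""


class UnreachableTargetError(QuadbindError, RuntimeError):
    """A requested saturation level cannot be reached at any feasible titrant excess."""


class InternalInvariantError(QuadbindError, RuntimeError):
    """A condition that should be mathematically impossible was observed."""
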