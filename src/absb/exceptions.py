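"""Exception hierarchy shared across the package."""


class AbsbError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(AbsbError, ValueError):
    """Fewer observations than free parameters (or other hard data minimum)."""


class InvalidParameterError(AbsbError, ValueError):
    """A user-supplied parameter is outside its admissible range."""


class SchemaError(AbsbError, ValueError):
    """A tabular input does not match its documented column schema."""


class RosterMismatchError(AbsbError, ValueError):
    """Conformers of one ensemble do not share an identical atom roster."""


class NoConvergenceError(AbsbError, RuntimeError):
    """No start of a multi-start nonlinear fit converged."""


class FlatProfileError(AbsbError, ValueError):
    """A CEST profile carries no exchange information (flat within tolerance)."""


class NumericalFailureError(AbsbError, RuntimeError):
    """A numerical primitive (e.g. a matrix exponential) returned non-finite values."""
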