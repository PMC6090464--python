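"""Exception hierarchy for the connectome-criticality pipeline."""


class ConncritError(Exception):
    """Base class for all package errors."""


class FormatError(ConncritError):
    """Malformed on-disk data (non-square matrix, unparseable tokens)."""


class ValidationError(ConncritError):
    """Data violates a connectivity-matrix invariant (range, symmetry)."""


class ParameterError(ConncritError, ValueError):
    """A parameter is outside its admissible domain."""


class DomainError(ConncritError, ValueError):
    """Sample values fall outside the fit domain."""


class InsufficientDataError(ConncritError):
    """Too few values to fit a distribution model."""


class CapacityError(ConncritError):
    """Problem size exceeds an exact-enumeration limit."""


class FitError(ConncritError):
    """Numerical optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(ConncritError):
    """Heterogeneous or incomplete records passed to a table writer."""
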