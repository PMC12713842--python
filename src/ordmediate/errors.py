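"""Exception hierarchy for ordmediate."""


class OrdmediateError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(OrdmediateError):
    """A declared column is missing or a role map is inconsistent."""


class ValidationError(OrdmediateError):
    """Input values violate a documented invariant (e.g. outcome outside 0-3)."""


class DegenerateColumnError(OrdmediateError):
    """A column has zero variance where positive variance is required."""


class InsufficientDataError(OrdmediateError):
    """Too few complete observations for the requested computation."""


class SingularDesignError(OrdmediateError):
    """The design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class ConvergenceError(OrdmediateError):
    """Iterative fitting failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StructuralError(OrdmediateError):
    """A mediation path references a coefficient absent from its fit."""
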