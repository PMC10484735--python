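"""Exception hierarchy used across all fitting and I/O modules."""


class Gp32FilamentError(Exception):
    """Base class for package-specific errors."""


class DomainError(Gp32FilamentError, ValueError):
    """Input outside the mathematical domain of a model."""


class InsufficientDataError(Gp32FilamentError, ValueError):
    """Too few samples to perform the requested fit."""


class FitFailureError(Gp32FilamentError, RuntimeError):
    """Nonlinear least squares did not converge; message carries diagnostics."""


class SchemaError(Gp32FilamentError, ValueError):
    """A required column is missing from an input file."""


class ValidationError(Gp32FilamentError, ValueError):
    """Parsed data violates a structural invariant (e.g. non-monotone time)."""
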