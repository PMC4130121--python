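"""Exception hierarchy shared across the package."""


class ClampvalError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ClampvalError, ValueError):
    """An input value is outside the mathematical/physiological domain."""


class UnitsError(ClampvalError, ValueError):
    """An unknown or inconsistent unit label was supplied."""


class ValidityError(ClampvalError, ValueError):
    """An input violates the validity bounds of a formula (e.g. Friedewald TG)."""


class InsufficientDataError(ClampvalError, ValueError):
    """Too few observations for the requested computation."""


class ConvergenceError(ClampvalError, RuntimeError):
    """An iterative estimator failed to converge."""


class SchemaError(ClampvalError, ValueError):
    """Tabular input does not match the expected column schema."""


class ConfigurationError(ClampvalError, ValueError):
    """A configuration object is internally inconsistent."""
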