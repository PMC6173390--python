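"""Exception hierarchy shared across the package."""


class SSBReformError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SSBReformError):
    """Invalid configuration object or unknown option value."""


class DomainError(SSBReformError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class CalibrationError(SSBReformError):
    """Steady-state calibration failed for a named individual."""


class IntegrationError(SSBReformError):
    """The ODE integrator produced a non-finite or non-physical state."""


class ValidationError(SSBReformError):
    """A population table failed schema or invariant checks."""
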