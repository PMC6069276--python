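"""Exception hierarchy for the fluoride PBPK package."""


class FluokinError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FluokinError):
    """A model or scenario configuration is incomplete or inconsistent."""


class DomainError(FluokinError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class AgeRangeError(DomainError):
    """Requested age is outside the span on which a relation is defined."""


class InsufficientDurationError(FluokinError):
    """A simulation result does not cover enough days for the requested metric."""


class IntegrationError(FluokinError):
    """The ODE propagation produced an invalid state.

    Carries ``last_valid_time_min`` when known.
    """

    def __init__(self, message: str, last_valid_time_min: float | None = None):
        super().__init__(message)
        self.last_valid_time_min = last_valid_time_min


class NotConvergedError(FluokinError):
    """An iterative procedure (root finding) failed to converge.

    Carries the final ``residual`` when known.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CalibrationError(FluokinError):
    """Model calibration against validation cohorts failed."""


class DoubleCalibrationError(CalibrationError):
    """The empirical adjustment factor was applied twice to the same value."""


class FixtureIntegrityError(FluokinError):
    """A bundled data fixture failed its checksum verification."""
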