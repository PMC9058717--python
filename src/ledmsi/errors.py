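"""Exception hierarchy for the ledmsi package."""


class LedmsiError(Exception):
    """Base class for all package-specific errors."""


class CaptureError(LedmsiError):
    """A frame capture failed; carries the identity of the failing band."""

    def __init__(self, message: str, band: str | None = None):
        super().__init__(message)
        self.band = band


class CalibrationError(LedmsiError):
    """Intensity calibration did not converge; carries the last state."""

    def __init__(self, message: str, duty: float | None = None,
                 mgv: float | None = None, iterations: int | None = None):
        super().__init__(message)
        self.duty = duty
        self.mgv = mgv
        self.iterations = iterations


class DegenerateStackError(LedmsiError):
    """The band stack has zero total variance; PCA is undefined."""


class FormatError(LedmsiError):
    """A file could not be parsed in the expected format."""


class ConfigError(LedmsiError):
    """A run configuration failed schema validation."""
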