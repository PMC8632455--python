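"""Exception types shared across the package."""


class RamanFFError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RamanFFError, ValueError):
    """An input object violates a documented invariant."""


class FormatError(RamanFFError, ValueError):
    """A file could not be parsed as the expected text format."""


class CalibrationError(RamanFFError, RuntimeError):
    """Generator calibration failed to reach the requested targets."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class TrainingError(RamanFFError, RuntimeError):
    """Neural-network training produced a non-finite loss."""
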