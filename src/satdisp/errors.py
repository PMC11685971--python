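"""Exception types shared across the pipeline."""


class SatdispError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SatdispError, ValueError):
    """An invalid configuration value; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class DomainError(SatdispError, ValueError):
    """An argument outside its mathematical domain."""


class GeometryError(SatdispError, ValueError):
    """Invalid or degenerate geometry input."""


class FitError(SatdispError, RuntimeError):
    """A model fit failed or is undefined for the given data."""


class StageError(SatdispError, RuntimeError):
    """A pipeline stage aborted; carries the stage name and a reason."""

    def __init__(self, stage: str, reason: str):
        self.stage = stage
        self.reason = reason
        super().__init__(f"pipeline stage '{stage}' failed: {reason}")
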