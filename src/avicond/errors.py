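"""Exception hierarchy shared across the package."""


class AvicondError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AvicondError):
    """Input table does not match the expected column schema."""


class ValidationError(AvicondError):
    """A cell failed validation (negative, non-numeric, out of range)."""


class IntegrityError(AvicondError):
    """Structural inconsistency, e.g. duplicate month keys."""


class UndefinedRateError(AvicondError):
    """A rate or ratio has a zero denominator."""


class InsufficientDataError(AvicondError):
    """Too few observations to run the requested statistic."""


class DegenerateSampleError(AvicondError):
    """Sample has zero variance where a test statistic needs spread."""


class ConfigError(AvicondError):
    """Invalid simulation or pipeline configuration."""


class PipelineError(AvicondError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
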