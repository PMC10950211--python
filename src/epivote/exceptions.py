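"""Exception hierarchy shared across the package."""


class EpivoteError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EpivoteError, ValueError):
    """A simulation or run configuration violates its invariants."""


class SchemaError(EpivoteError, ValueError):
    """A table fails schema validation (missing columns, bad ranges, duplicate keys)."""


class EstimationError(EpivoteError, RuntimeError):
    """A model could not be estimated (singular design, degenerate input)."""


class MatchingError(EpivoteError, RuntimeError):
    """Propensity-score matching produced no admissible sample."""


class PipelineError(EpivoteError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
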