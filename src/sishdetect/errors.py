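"""Exception types shared across the pipeline."""


class SishDetectError(Exception):
    """Base class for all package errors."""


class ParameterError(SishDetectError, ValueError):
    """An argument violates a documented precondition."""


class GenerationError(SishDetectError, RuntimeError):
    """Synthetic scene placement failed under the configured constraints."""


class EstimationError(SishDetectError, RuntimeError):
    """Stain estimation could not proceed (e.g. too few tissue pixels)."""


class SchemaError(SishDetectError, KeyError):
    """A required table column is missing."""


class MetricsError(SishDetectError, ValueError):
    """Detection metrics are undefined for the given counts."""


class ConfigError(SishDetectError, ValueError):
    """A configuration file or object is invalid."""


class CheckpointError(SishDetectError, RuntimeError):
    """A model checkpoint could not be loaded."""
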