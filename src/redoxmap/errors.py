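"""Exception hierarchy shared across modules."""


class RedoxmapError(Exception):
    """Base class for all package errors."""


class ConfigError(RedoxmapError):
    """Invalid configuration value; message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field '{field}': {message}")


class SchemaError(RedoxmapError):
    """Input table is missing a required column."""


class ParseError(RedoxmapError):
    """Malformed input file (FASTA/TSV)."""


class ValidationError(RedoxmapError):
    """Input data violates a contract (negative intensity, bad position, ...)."""


class NormalizationError(RedoxmapError):
    """Normalization cannot proceed (zero reference, unmapped channel, ...)."""


class UnimodalDensityError(RedoxmapError):
    """Density has fewer than two local maxima; no valley boundary exists."""


class DegenerateValuesError(RedoxmapError):
    """Too few or constant values for density estimation."""
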