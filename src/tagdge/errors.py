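"""Exception types shared across the package."""


class TagDGEError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TagDGEError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(TagDGEError, ValueError):
    """Malformed input file (FASTQ/TSV record or missing column)."""


class InputError(TagDGEError, ValueError):
    """Inconsistent inputs to an analysis operation."""


class DomainError(TagDGEError, ValueError):
    """Argument outside the mathematical domain of a statistic."""


class UndefinedStatisticError(TagDGEError, ZeroDivisionError):
    """A requested statistic is undefined (e.g. percentage of zero)."""
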