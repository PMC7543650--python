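"""Exception hierarchy shared across the pipeline."""


class SiatDcmError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SiatDcmError):
    """Invalid generator or pipeline configuration (non-positive counts/scales)."""


class SchemaError(SiatDcmError):
    """Input table/parameter schema violation (unknown names, bad columns)."""


class InsufficientDataError(SiatDcmError):
    """Too few observations to compute the requested statistic."""


class DegenerateInputError(SiatDcmError):
    """Zero-variance or otherwise degenerate input."""


class StabilityError(SiatDcmError):
    """Neural dynamics unstable for the requested parameters."""


class CoverageError(SiatDcmError):
    """Missing subject/model combinations or empty groups."""
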