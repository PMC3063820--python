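"""Exception types shared across the pipeline stages."""


class QpcrError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(QpcrError, ValueError):
    """Invalid simulation or analysis parameters."""


class InsufficientDataError(QpcrError, ValueError):
    """Too few usable observations for the requested computation."""


class QualityError(QpcrError, RuntimeError):
    """All reactions rejected by a quality filter."""


class NormalizationError(QpcrError, ValueError):
    """No reference genes available for normalization."""


class ConfigError(QpcrError, ValueError):
    """Invalid or incomplete pipeline configuration."""


class TableFormatError(QpcrError, ValueError):
    """A CSV table does not conform to the documented dialect."""
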