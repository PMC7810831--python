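"""Exception hierarchy for the resptrend pipeline.

Every stage raises a subclass of :class:`RespTrendError` so callers can
distinguish pipeline failures from programming errors.
"""


class RespTrendError(Exception):
    """Base class for all resptrend errors."""


class ConfigurationError(RespTrendError):
    """Invalid generator or pipeline configuration."""


class FormatError(RespTrendError):
    """A required column or field is missing from an input file."""


class EmptyResultError(RespTrendError):
    """A filtering or generation step produced no records."""


class CovariateError(RespTrendError):
    """Climate or SOC matching failed for one or more records."""


class DegenerateSeriesError(RespTrendError):
    """A statistic is undefined on the given series (e.g. zero variance)."""


class ModelError(RespTrendError):
    """Model fitting failed (rank deficiency, bad weights, domain error)."""
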