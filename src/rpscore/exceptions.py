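"""Exception hierarchy for rpscore.

All domain errors derive from :class:`RPSError` so callers can catch the
package's failures with one clause; each also subclasses the closest
builtin so generic handlers keep working.
"""


class RPSError(Exception):
    """Base class for all rpscore errors."""


class ConfigurationError(RPSError, ValueError):
    """A configuration object holds an invalid field value."""


class ValidationError(RPSError, ValueError):
    """An input violates a documented precondition."""


class MissingDataError(RPSError, ValueError):
    """A required feature value is absent from a record."""


class UndefinedMetricError(RPSError, ValueError):
    """A metric is undefined for the given labels (e.g. one class only)."""


class UndefinedIndicatorError(RPSError, ValueError):
    """A ratio indicator has a zero denominator."""


class UnsupportedIndicatorError(RPSError, ValueError):
    """An indicator was requested for an epoch that cannot provide it."""


class UnsupportedModelError(RPSError, ValueError):
    """An operation is undefined for the given model kind."""


class FittingError(RPSError, RuntimeError):
    """A model could not be fitted (e.g. single-class training labels)."""
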