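"""Exception hierarchy for actikin.

Every error raised by the library derives from :class:`ActikinError` so that
callers (and the CLI) can distinguish library failures from programming bugs.
"""


class ActikinError(Exception):
    """Base class for all actikin errors."""


class InvalidParameterError(ActikinError, ValueError):
    """A kinetic parameter is non-positive, non-finite, or otherwise invalid."""


class InvalidContextError(ActikinError, ValueError):
    """A reconstitution context has inconsistent or non-physical fields."""


class UnknownConditionError(ActikinError, KeyError):
    """The named reconstitution condition has no built-in definition."""


class InvalidNoiseError(ActikinError, ValueError):
    """A noise specification contains negative parameters."""


class DoubleCorrectionError(ActikinError):
    """An orientation correction was applied to an already-corrected rate."""


class DegenerateTimecourseError(ActikinError, ValueError):
    """A time course has fewer than two distinct time points."""


class DegenerateDataError(ActikinError, ValueError):
    """Rate data carry no usable signal (e.g. all rates zero)."""


class DesignError(ActikinError, ValueError):
    """The concentration design cannot identify the requested model."""


class ConvergenceError(ActikinError, RuntimeError):
    """No optimizer restart reached the convergence tolerance."""


class ConfigError(ActikinError, ValueError):
    """A run configuration is missing or has an invalid key."""


class ParseError(ActikinError, ValueError):
    """An input table could not be parsed."""
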