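"""Exception hierarchy shared across the package.

Every error raised deliberately by reefwave derives from :class:`ReefwaveError`,
so callers (and the CLI) can distinguish configuration, data, and numeric
failures from programming errors.
"""


class ReefwaveError(Exception):
    """Base class for all reefwave errors."""


class InvalidConfigError(ReefwaveError):
    """A configuration value is missing, inconsistent, or out of its domain."""


class AlignmentError(ReefwaveError):
    """Two series that must share a time grid do not."""


class EmptySeriesError(ReefwaveError):
    """An operation received, or would produce, a series with no usable samples."""


class DegenerateInputError(ReefwaveError):
    """Input is formally valid but statistically degenerate (e.g. constant series)."""


class InfeasibleChemistryError(ReefwaveError):
    """The requested carbonate-system state has no physical solution."""


class InsufficientNullError(ReefwaveError):
    """Too few randomizations/surrogates to resolve the requested significance level."""


class FormatError(ReefwaveError):
    """An input file does not conform to the documented format."""
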