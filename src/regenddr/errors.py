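"""Exception hierarchy for the pipeline.

Every anticipated failure mode raises a subclass of :class:`RegenDDRError`
so callers (and the CLI) can distinguish pipeline errors from bugs.
"""


class RegenDDRError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RegenDDRError):
    """A configuration object violates its invariants."""


class SchemaError(RegenDDRError):
    """An input table does not conform to the documented dialect."""


class EmptyInputError(RegenDDRError):
    """An operation received an empty collection where data is required."""


class DegenerateAnchorError(RegenDDRError):
    """The anchor profile is constant, so correlation is undefined."""


class InsufficientDataError(RegenDDRError):
    """Fewer shared timepoints than the configured minimum."""


class DegenerateDispersionError(RegenDDRError):
    """A standard deviation required to be positive is not."""


class NormalizationError(RegenDDRError):
    """A normalization denominator is zero or missing."""


class MalformedInputError(RegenDDRError):
    """A record or value violates its domain constraints."""


class DegenerateTableError(RegenDDRError):
    """A contingency table has an all-zero row or column."""


class EnumerationLimitError(RegenDDRError):
    """A contingency table is too large for full exact enumeration."""
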