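"""Exception hierarchy for the dissimogram package."""


class DissimogramError(Exception):
    """Base class for all package errors."""


class SchemaError(DissimogramError):
    """An input table does not have the expected columns."""


class ValidationError(DissimogramError):
    """An input table has the right shape but invalid content."""


class EmptySelectionError(DissimogramError):
    """A filter (year, region, plot) selected no records."""


class AlignmentError(DissimogramError):
    """Two containers that must share an axis (e.g. plot sets) do not."""


class FitError(DissimogramError):
    """A model fit could not be attempted (insufficient or degenerate data)."""


class ConfigError(DissimogramError):
    """A configuration value violates its invariants."""
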