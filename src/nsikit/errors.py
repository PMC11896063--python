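"""Exception hierarchy for the succession-index pipeline.

Everything raised on purpose derives from :class:`NsikitError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class NsikitError(Exception):
    """Base class for all errors raised by nsikit."""


class SchemaError(NsikitError):
    """A required column is missing from an input table."""


class RowParseError(NsikitError):
    """A cell in an input table could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class StageCodeError(RowParseError):
    """An observed land-cover code is not in the stage vocabulary."""


class IntegrityError(NsikitError):
    """Cross-record consistency violated (duplicate keys, orphan references)."""


class ConfigurationError(NsikitError):
    """A configuration value is inconsistent with the data it is applied to."""


class NonMonotoneSeriesError(NsikitError):
    """A plot series regresses to an earlier seral stage."""


class UndefinedIndexError(NsikitError):
    """The succession index is undefined (no samples in the stratum)."""
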