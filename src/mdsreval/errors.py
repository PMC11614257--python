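"""Exception hierarchy for the MDSR evaluation toolkit.

Every error raised on bad input derives from :class:`MdsrEvalError`, so a
pipeline driver can catch one type.  Schema problems (a missing column)
are distinguished from row-level validation problems (a bad value in an
otherwise well-formed table) and from cross-field consistency problems
(counts that do not add up).
"""


class MdsrEvalError(Exception):
    """Base class for all errors raised by mdsreval."""


class SchemaError(MdsrEvalError):
    """A table is structurally wrong: a required column is missing."""


class RecordValidationError(MdsrEvalError):
    """A single row/record carries an invalid value."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        super().__init__(message)


class ConsistencyError(MdsrEvalError):
    """Cross-field arithmetic does not hold (e.g. subcounts != total)."""


class ConfigError(MdsrEvalError):
    """Invalid configuration: weights not summing to 1, bad probabilities."""


class UndefinedIndicatorError(MdsrEvalError):
    """A computation requires an indicator whose denominator was zero."""

    def __init__(self, indicators: list[str]):
        self.indicators = list(indicators)
        super().__init__(
            "undefined indicator(s) due to zero denominator: " + ", ".join(indicators)
        )
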