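"""Exception hierarchy shared across the package."""


class SpliceScreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SpliceScreenError):
    """A table is missing required columns or is otherwise malformed."""


class IntegrityError(SpliceScreenError):
    """Data violates a structural invariant (duplicate ids, orphan references)."""


class TableParseError(SpliceScreenError):
    """A cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class InvalidWellError(SpliceScreenError):
    """A well cannot yield a ratio (firefly <= 0)."""


class MissingConditionError(SpliceScreenError):
    """No usable wells remain for a condition summary."""


class DegenerateControlError(SpliceScreenError):
    """Positive- and negative-control effects coincide; hit calling impossible."""


class ConfigError(SpliceScreenError):
    """An analysis or generator parameter is out of its allowed range."""


class UnquantifiableLaneError(SpliceScreenError):
    """A gel lane has zero total signal and cannot be quantified."""
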