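"""Exception hierarchy shared across the triage pipeline."""


class TriageError(Exception):
    """Base class for all package-specific errors."""


class HgvsParseError(TriageError, ValueError):
    """A cDNA notation string could not be parsed; the message names the token."""


class SchemaError(TriageError, ValueError):
    """An input table is missing mandatory columns or has a malformed layout."""


class RowError(TriageError, ValueError):
    """A single table row failed validation; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"row {line}: {message}" if line is not None else message)


class DataError(TriageError, ValueError):
    """A value is outside its documented domain (e.g. allele_number = 0)."""


class ConfigError(TriageError, ValueError):
    """A configuration value is invalid or internally inconsistent."""


class InsufficientDataError(TriageError, ValueError):
    """An operation was asked to decide without the inputs it needs."""


class ClassificationError(TriageError, ValueError):
    """A record cannot be classified/subclassified from the evidence given."""


class ContractError(TriageError, ValueError):
    """An operation was invoked outside its stated precondition."""
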