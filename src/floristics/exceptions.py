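"""Exception hierarchy for floristics."""


class FloristicsError(Exception):
    """Base class for all package errors."""


class SchemaError(FloristicsError):
    """An input table is missing required columns or has a malformed header."""


class ConsistencyError(FloristicsError):
    """Input records violate a taxonomic or structural invariant."""


class EmptyInputError(FloristicsError):
    """An operation received an empty table, set, or group where data is required."""


class DomainError(FloristicsError):
    """An argument is outside the operation's valid domain (e.g. k out of range)."""


class AlignmentError(FloristicsError):
    """Two inputs that must cover identical reserve sets do not."""
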