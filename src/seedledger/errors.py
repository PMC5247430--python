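"""Exception hierarchy shared by every seedledger module.

Exit codes mirror the CLI contract: 0 ok, 2 validation, 3 authorization,
4 not found.
"""


class SeedLedgerError(Exception):
    """Base class for all errors raised by the library."""

    exit_code = 2


class ValidationError(SeedLedgerError):
    """A record or argument violates a documented contract."""

    exit_code = 2

    def __init__(self, message: str, missing: tuple[str, ...] = ()):
        super().__init__(message)
        #: names of the mandatory fields that were absent, when applicable
        self.missing = tuple(missing)


class AuthorizationError(SeedLedgerError):
    """The logged-in account lacks the role required for the operation."""

    exit_code = 3


class NotFoundError(SeedLedgerError):
    """The addressed record does not exist."""

    exit_code = 4


class ConflictError(ValidationError):
    """Uniqueness violated (duplicate login or vocabulary value)."""


class DependencyError(ValidationError):
    """A prerequisite record is missing (e.g. ecotype before its species)."""


class InUseError(ValidationError):
    """Deletion refused because records still reference the entry."""

    def __init__(self, message: str, count: int):
        super().__init__(message)
        self.count = count


class CategoryError(ValidationError):
    """A value was used with the wrong feature/vocabulary category."""


class LockedError(ValidationError):
    """Edit attempted on a locked record."""


class ImmutableFeatureError(ValidationError):
    """Inherited genetic features can only be edited via their origin line."""


class SpeciesMismatchError(ValidationError):
    """Only intra-species crosses are permitted."""


class ConsistencyError(ValidationError):
    """Cross-record reference is inconsistent (foreign batch, foreign feature)."""


class PatternError(ValidationError):
    """Malformed search pattern (e.g. trailing bare escape character)."""


class FieldError(ValidationError):
    """Unknown search field; message lists the valid names."""


class FormatError(ValidationError):
    """An interchange document failed schema validation."""

    def __init__(self, message: str, location: str = ""):
        super().__init__(message)
        #: slash-separated JSON pointer to the offending value
        self.location = location


class VocabularyError(ValidationError):
    """A value is not present in the controlled vocabulary."""

    def __init__(self, message: str, unknown: dict[str, list[str]] | None = None):
        super().__init__(message)
        #: category name -> values missing from the vocabulary
        self.unknown = unknown or {}


class GuidelinesNotConfiguredError(SeedLedgerError):
    """The lab-guidelines document path has not been configured yet."""

    exit_code = 2


class RendererUnavailableError(SeedLedgerError):
    """PNG rendering unavailable; DOT output is always possible."""

    exit_code = 2
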