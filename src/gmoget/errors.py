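"""Exception hierarchy for gmoget.

Structural problems found by the validator are *data* (Violation records),
not exceptions; exceptions are reserved for operations that cannot return
a meaningful result (bad insertions, unparseable input, unknown lookups).
"""


class GmoGetError(Exception):
    """Base class for all gmoget errors."""


class ThesaurusError(GmoGetError):
    """Invalid thesaurus manipulation (bad insert, exhausted id space)."""


class DuplicateIdError(ThesaurusError):
    pass


class DuplicateNameError(ThesaurusError):
    pass


class UnknownParentError(ThesaurusError):
    pass


class CycleError(ThesaurusError):
    pass


class LevelError(ThesaurusError):
    """Term level inconsistent with its parent (or > 4, or second root)."""


class IdSpaceExhaustedError(ThesaurusError):
    pass


class UnknownTermError(GmoGetError):
    """A referenced term id does not exist in the thesaurus."""


class NameSyntaxError(GmoGetError):
    """An element designation cannot be parsed at all."""


class UnknownPrefixError(NameSyntaxError):
    pass


class MissingDonorError(NameSyntaxError):
    pass


class OboParseError(GmoGetError):
    """Malformed OBO input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownNamespaceError(GmoGetError):
    """resolve_xref called with a namespace the index does not know."""


class RegistryError(GmoGetError):
    """Malformed donor-registry or prefix-registry data."""
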