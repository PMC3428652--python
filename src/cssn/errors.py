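"""Exception hierarchy for the cssn package."""


class CssnError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CssnError):
    """A malformed record in an input file.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(CssnError):
    """Input records are individually well-formed but mutually inconsistent
    (duplicate identifiers, unresolvable semantic-type names, cycles)."""


class UnknownSemanticTypeError(CssnError, KeyError):
    """A semantic type was referenced by a name or TUI not present in the network."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return Exception.__str__(self)


class DomainError(CssnError):
    """An operation was applied to a semantic type outside its defined domain
    (e.g. an axis query on a non-chemical type)."""


class SpecError(CssnError):
    """A synthetic-data specification references unknown types or is malformed."""
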