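"""Exception hierarchy shared across the pipeline stages."""


class FamvarkitError(Exception):
    """Base class for all package errors."""


class IdentifierError(FamvarkitError, KeyError):
    """An individual/marker/sample id does not exist where referenced."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class ParseError(FamvarkitError, ValueError):
    """A file could not be parsed; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConfigurationError(FamvarkitError, ValueError):
    """Inconsistent configuration, e.g. pedigree/sample mismatch."""


class DomainError(FamvarkitError, ValueError):
    """Operation called outside its mathematical domain."""


class CapacityError(FamvarkitError, RuntimeError):
    """Exact enumeration would exceed the configured bit limit.

    Raised instead of silently approximating; callers should analyse a
    sub-pedigree or raise the limit explicitly.
    """


class LdUndefinedError(DomainError):
    """r^2 requested for a monomorphic (zero-variance) marker."""
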