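"""Exception hierarchy for the tea-catechin PBPK package."""


class TeapbpkError(Exception):
    """Base class for all package errors."""


class LookupError_(TeapbpkError, KeyError):
    """Unknown catechin, species, study or compartment identifier."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class DomainError(TeapbpkError, ValueError):
    """An argument is outside the physically meaningful domain."""


class ParameterNotPublishedError(TeapbpkError):
    """Pharmacokinetic parameters for this catechin/species were never
    published; the registry refuses to fabricate them."""


class ConsistencyError(TeapbpkError):
    """Model components refer to different catechins or species."""


class IntegrationError(TeapbpkError):
    """The ODE solver failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ParseError(TeapbpkError, ValueError):
    """A data file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line
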