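"""Exception hierarchy shared across the package.

Each family maps to a stable process exit code in the CLI so that shell
pipelines can distinguish malformed input from statistical failure modes.
"""

from __future__ import annotations


class MetacovError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MetacovError):
    """A required column or field is missing from an input table."""


class ParseError(MetacovError):
    """A cell could not be parsed (non-numeric or missing value)."""


class ValidationError(MetacovError):
    """Input violates a documented invariant (duplicates, bad ranges...)."""


class UnknownLabelError(ValidationError, KeyError):
    """A requested group/sex/module label does not exist in the data."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return ValidationError.__str__(self)


class SampleSizeError(ValidationError):
    """Too few observations for the requested operation (correlation needs >=3)."""


class ConfigError(ValidationError):
    """A configuration object violates its invariants."""


class ConvergenceError(MetacovError):
    """Consensus clustering failed to converge within ``max_iter``.

    Carries the last agreement matrix for inspection.
    """

    def __init__(self, message: str, agreement=None):
        super().__init__(message)
        self.agreement = agreement


class DegenerateInputError(MetacovError):
    """Input is degenerate for the operation (zero variance, empty network...)."""


#: CLI exit-code families (2=schema/parse, 3=validation/sample-size,
#: 4=convergence, 5=degenerate input).
EXIT_SCHEMA = 2
EXIT_VALIDATION = 3
EXIT_CONVERGENCE = 4
EXIT_DEGENERATE = 5


def exit_code_for(exc: BaseException) -> int:
    """Map an exception to its CLI exit-code family (1 for anything else)."""
    if isinstance(exc, (SchemaError, ParseError)):
        return EXIT_SCHEMA
    if isinstance(exc, ValidationError):
        return EXIT_VALIDATION
    if isinstance(exc, ConvergenceError):
        return EXIT_CONVERGENCE
    if isinstance(exc, DegenerateInputError):
        return EXIT_DEGENERATE
    return 1
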