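"""Exception hierarchy.

``ValidationError`` covers malformed inputs (CLI exit code 2), ``NumericalError``
covers solver failures (CLI exit code 3).
"""


class PitchspaceError(Exception):
    """Base class for all package errors."""


class ValidationError(PitchspaceError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A file does not match its declared column schema."""


class NumericalError(PitchspaceError):
    """A numerical procedure failed (no root bracketed, divergent fit, ...)."""
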