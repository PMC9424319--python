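"""Exception hierarchy.

``ValidationError`` covers bad user input (malformed files, out-of-range
parameters, missing identifiers) and maps to exit code 2 in the CLI;
anything else is a runtime failure (exit code 1).
"""


class SigforgeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SigforgeError, ValueError):
    """Invalid input: bad parameter, malformed file, violated invariant."""


class FormatError(ValidationError):
    """A file does not conform to its expected format."""


class GeneLookupError(ValidationError, KeyError):
    """Requested gene or sample identifiers are absent from a container."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return ValueError.__str__(self)


class DegenerateDataError(ValidationError):
    """Data are degenerate for the requested operation (e.g. zero variance)."""
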