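"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems (bad input
content, violated preconditions) exit 2, I/O problems exit 3.
"""


class CoderepError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CoderepError, ValueError):
    """Input content or parameters violate a documented contract."""


class ParseError(ValidationError):
    """A text input could not be parsed; carries the offending line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class SizingError(ValidationError):
    """A synthetic genome is too small for the requested layout."""
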