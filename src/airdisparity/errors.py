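"""Exception hierarchy.

All errors raised by this package derive from :class:`ValueError` so that
callers who do not care about the distinction can catch a single type.
"""


class ValidationError(ValueError):
    """An input violates a structural precondition (shape, range, label)."""


class ShapeError(ValidationError):
    """Two gridded inputs do not share the same shape."""


class DomainError(ValueError):
    """A quantity is mathematically undefined for the given inputs
    (e.g. a relative disparity when nobody is exposed)."""


class ParseError(ValueError):
    """A file on disk does not conform to the expected schema."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
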