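"""Exception types shared across the package."""
from __future__ import annotations


class SchemaError(ValueError):
    """An input table violates its schema.

    Carries optional file path and 1-based line number (header is line 1)
    so command-line users can locate the offending row.
    """

    def __init__(self, message: str, *, path: str | None = None,
                 line: int | None = None) -> None:
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f":{line}"
        if prefix:
            message = f"{prefix}: {message}"
        super().__init__(message)


class InternalInvariantError(RuntimeError):
    """An internal consistency check failed; indicates a bug, not bad input."""
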