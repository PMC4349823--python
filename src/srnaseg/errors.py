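"""Exception hierarchy.

Parse errors carry file/line context where available; content errors signal
structurally valid input that violates a domain invariant.
"""


class SrnasegError(Exception):
    """Base class for all package errors."""


class ParseError(SrnasegError):
    """A file could not be parsed under the requested dialect."""

    def __init__(self, message, path=None, line=None):
        ctx = []
        if path is not None:
            ctx.append(str(path))
        if line is not None:
            ctx.append(f"line {line}")
        prefix = f"[{': '.join(ctx)}] " if ctx else ""
        super().__init__(prefix + message)
        self.path = path
        self.line = line


class ContentError(SrnasegError):
    """Input parsed but its content violates an invariant."""


class UndefinedInputError(SrnasegError):
    """A quantity is undefined for the given input (e.g. all-zero frequency vector)."""
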