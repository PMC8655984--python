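"""Exception hierarchy.

Every error raised by the library derives from :class:`RWRScreenError`, so
callers (and the CLI) can distinguish configuration mistakes, malformed
input and numerical failure without string matching.
"""


class RWRScreenError(Exception):
    """Base class for all rwrscreen errors."""


class ConfigError(RWRScreenError):
    """A parameter is outside its admissible range."""


class InputFormatError(RWRScreenError):
    """A file could not be parsed; carries line context where available."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class RejectedEdgeError(InputFormatError):
    """An edge record is unusable (non-numeric or non-positive score)."""


class MissingNodeError(RWRScreenError):
    """A gene identifier is not present in the network."""


class EmptyInputError(RWRScreenError):
    """An input collection that must be non-empty is empty."""


class ConvergenceError(RWRScreenError):
    """Power iteration did not converge; carries the last residual."""

    def __init__(self, message: str, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(message)
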