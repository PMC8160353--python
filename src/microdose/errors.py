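"""Exception hierarchy shared by all pipeline stages.

Degenerate numerical inputs raise explicit errors instead of returning NaN,
so that a pathological spectrum cannot silently propagate into an RBE value.
"""


class MicrodoseError(Exception):
    """Base class for all package errors."""


class DomainError(MicrodoseError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateInputError(MicrodoseError, ValueError):
    """Input is formally valid but numerically degenerate (empty, all-zero...)."""


class ConfigurationError(MicrodoseError):
    """Inconsistent or incomplete configuration (missing table, unknown key...)."""


class CalibrationError(MicrodoseError):
    """A beam-model calibration failed to reach its target."""


class ParseError(MicrodoseError):
    """A text input file could not be parsed.

    Parameters
    ----------
    message : str
    path : str, optional
    line : int, optional
        1-based line number of the offending line.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f"{path}:"
        if line is not None:
            loc += f"{line}:"
        super().__init__(f"{loc} {message}" if loc else message)
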