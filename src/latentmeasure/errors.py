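"""Exception hierarchy shared by all modules.

``ValidationError`` signals malformed input (CLI exit code 2);
``NumericalError`` signals a failure of the computation itself, e.g. a
reducible operator or a diverging iteration (CLI exit code 1).
"""


class ValidationError(ValueError):
    """Input violates a documented precondition or format contract."""


class ParseError(ValidationError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NumericalError(RuntimeError):
    """A numerical procedure failed (non-convergence, ill-posed spectrum)."""


class ReducibleOperatorError(NumericalError):
    """The chain has more than one closed communicating class, so the
    eigenvalue-1 eigenspace is degenerate and the invariant measure is not
    unique.  ``blocks`` lists the state sets of the closed classes."""

    def __init__(self, message: str, blocks: list[list[int]]):
        self.blocks = blocks
        super().__init__(message)
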