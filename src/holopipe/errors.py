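"""Exception hierarchy used across the pipeline.

The CLI maps these onto exit codes: validation errors exit 2, parse
errors 3, stage failures 4.
"""


class HolopipeError(Exception):
    """Base class for all package errors."""


class ValidationError(HolopipeError, ValueError):
    """A parameter or input violates a documented precondition."""


class ParseError(HolopipeError, ValueError):
    """A file does not conform to its expected dialect."""


class NoSignalError(HolopipeError):
    """A k-mer spectrum carries no usable coverage peak (pure error mass)."""


class FitError(HolopipeError):
    """An optimizer failed; carries the last residual norm when known."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class StageError(HolopipeError):
    """A pipeline stage failed; names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
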