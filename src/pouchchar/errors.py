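"""Exception hierarchy shared across the package."""


class PouchCharError(Exception):
    """Base class for all package errors."""


class ValidationError(PouchCharError, ValueError):
    """An input violates a documented precondition or invariant."""


class AlignmentError(PouchCharError, ValueError):
    """Two series that must share a time/size grid do not."""


class UndefinedNormalizationError(PouchCharError, ZeroDivisionError):
    """A normalization denominator is zero (e.g. zero total release)."""


class NeedsMoreTapsError(PouchCharError, RuntimeError):
    """Tapped-density series exhausted before the 2% stopping rule was met."""


class StageError(PouchCharError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
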