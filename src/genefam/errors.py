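"""Exception hierarchy shared by all genefam modules."""


class GenefamError(Exception):
    """Base class for all package errors."""


class ValidationError(GenefamError):
    """An input violates a documented precondition or invariant."""


class SaturationError(GenefamError):
    """A substitution proportion exceeds the Jukes-Cantor correction domain."""


class StageError(GenefamError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
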