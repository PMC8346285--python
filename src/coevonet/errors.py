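"""Exception hierarchy shared across the package."""


class CoevonetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CoevonetError, ValueError):
    """An input violated a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file could not be parsed; the message names the offending line."""


class PipelineError(CoevonetError):
    """A pipeline stage failed; ``stage`` names it, ``__cause__`` holds the reason."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
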