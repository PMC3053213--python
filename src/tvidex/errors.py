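"""Exception hierarchy shared across the pipeline."""


class TvidexError(Exception):
    """Base class for all package errors."""


class ParseError(TvidexError):
    """A file could not be parsed (names the offending row/column)."""


class ValidationError(TvidexError):
    """Input data violates a documented invariant or precondition."""


class ConfigError(TvidexError):
    """The pipeline configuration is invalid or references missing paths."""


class StageError(TvidexError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
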