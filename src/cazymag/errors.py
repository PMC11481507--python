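"""Exception hierarchy shared across the pipeline stages."""


class CazymagError(Exception):
    """Base class for all package errors."""


class FormatError(CazymagError):
    """A table or tree file violates the expected dialect (missing column, bad token)."""


class ValidationError(CazymagError):
    """A parsed value violates a domain invariant (range, uniqueness, foreign key)."""


class ConfigurationError(CazymagError):
    """An option value outside its allowed set (unknown mode, bad level)."""


class StageError(CazymagError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
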