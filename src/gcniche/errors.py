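"""Exception hierarchy shared across the package."""


class GCNicheError(Exception):
    """Base class for all package errors."""


class FormatError(GCNicheError):
    """A file does not conform to its expected on-disk layout."""


class ValidationError(GCNicheError):
    """Parsed data violates a structural invariant (duplicates, negatives, mismatched pairing)."""


class ParameterError(GCNicheError):
    """A configuration value or function argument is out of its admissible range."""


class AmbiguityError(GCNicheError):
    """More than one annotation rule fired for the same neighborhood."""


class StageError(GCNicheError):
    """A pipeline stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause!r}")
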