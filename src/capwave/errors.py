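"""Exception hierarchy for capwave."""


class CapwaveError(Exception):
    """Base class for all capwave errors."""


class ValidationError(CapwaveError, ValueError):
    """An argument or configuration violates a documented precondition."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but degenerate for the requested operation
    (constant sequence under min-max scaling, zero-variance t-test, ...)."""


class SchemaError(CapwaveError, OSError):
    """A dataset or checkpoint container does not match the expected schema."""


class TrainingDivergedError(CapwaveError, RuntimeError):
    """Optimization produced a non-finite loss."""
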