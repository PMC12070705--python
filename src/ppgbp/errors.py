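"""Exception types shared across the pipeline."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class DegenerateSignalError(ValueError):
    """The signal carries no usable information (e.g. constant samples)."""


class InsufficientSignalError(ValueError):
    """Too few beats / R-peaks for the requested analysis."""


class SchemaError(ValueError):
    """A table does not match the schema an operation was fitted with."""


class EmptyResultError(RuntimeError):
    """Every candidate was rejected; nothing is left to analyse."""


class IllConditionedError(RuntimeError):
    """A linear system is numerically singular (e.g. duplicated GP inputs
    with conflicting targets and zero observation noise)."""
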