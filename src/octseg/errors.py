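"""Exception types shared across the package."""


class OctSegError(Exception):
    """Base class for package errors."""


class ParameterError(OctSegError, ValueError):
    """A configuration or simulation parameter violates an invariant."""


class ValidationError(OctSegError, ValueError):
    """Input data violates a structural precondition (shape, ordering, ...)."""


class BoundaryCrossingError(ValidationError):
    """Two layer boundaries cross; carries the offending column and pair."""

    def __init__(self, column: int, upper: str, lower: str):
        self.column = int(column)
        self.pair = (upper, lower)
        super().__init__(
            f"boundaries '{upper}' and '{lower}' cross at column {column}"
        )


class UnsupportedContentError(ValidationError):
    """A mask contains classes an operation cannot handle (cysts/collapse)."""


class LabelError(ValidationError):
    """A target mask contains a class id outside the score map's range."""


class DataError(OctSegError):
    """A dataset does not contain the records a training regime requires."""


class StateError(OctSegError):
    """An operation was applied to an object in the wrong state."""


class DegenerateInputError(OctSegError, ValueError):
    """Statistical input is degenerate (e.g. all paired differences zero)."""


class ConfigError(OctSegError, ValueError):
    """Invalid model or pipeline configuration."""
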