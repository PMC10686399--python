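"""Exception hierarchy for the stare package."""


class StareError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StareError):
    """A file does not conform to the expected column schema."""


class DataError(StareError):
    """A file parses but violates a data invariant (ordering, emptiness)."""


class ParameterError(StareError):
    """An argument is outside its valid domain."""


class InsufficientDataError(StareError):
    """Too few samples (less than one full occlusion cycle) to fit."""


class UnusableEyeError(StareError):
    """One eye has no valid samples left after cleaning."""


class CalibrationError(StareError):
    """The fitted amplitude-to-dioptre curve is non-monotone or degenerate."""
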