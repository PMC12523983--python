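"""Exception hierarchy shared across the pipeline."""


class PhenotrackError(Exception):
    """Base class for all package errors."""


class DimensionError(PhenotrackError):
    """Image/table geometry does not match expectations."""


class SchemaError(PhenotrackError):
    """A required column or feature name is missing or mismatched."""


class DuplicateRecordError(PhenotrackError):
    """A (frame, track) pair appears more than once."""


class NoInputError(PhenotrackError):
    """An input container is empty."""


class ParameterError(PhenotrackError):
    """A parameter value is outside its valid domain."""


class CapacityError(PhenotrackError):
    """The simulated image is too small to place all requested cells."""
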