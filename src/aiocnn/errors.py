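"""Exception hierarchy.

Every error raised by the package derives from :class:`AioCnnError` so
callers can catch one type at the boundary.  Subclasses mirror the failure
modes of the pipeline: input validation, state misuse, sizing/layout,
model shape, degenerate labels, and experimental-design violations.
"""


class AioCnnError(Exception):
    """Base class for all package errors."""


class ValidationError(AioCnnError):
    """Input data violates a documented invariant (duplicates, negatives, ...)."""


class StateError(AioCnnError):
    """Operation applied to an object in the wrong state (e.g. log2 twice)."""


class SizingError(AioCnnError):
    """A gene list does not fit the requested image capacity or selection size."""


class MissingGeneError(AioCnnError):
    """A gene required by an ordering or pixel map is absent from the data."""


class BoundsError(AioCnnError):
    """A pixel coordinate lies outside the image configuration."""


class FormatError(AioCnnError):
    """An export format cannot represent the tensor (e.g. 2-channel PNG)."""


class ShapeError(AioCnnError):
    """Model input shape does not match the data."""


class DegenerateLabelsError(AioCnnError):
    """Training or evaluation needs >= 2 classes but got one."""


class DivergenceError(AioCnnError):
    """Training loss became non-finite."""


class StratificationError(AioCnnError):
    """A class has too few members for the requested fold count."""


class DesignError(AioCnnError):
    """Experimental-design violation (e.g. overlapping subject sets)."""


class ConfigError(AioCnnError):
    """Invalid simulation or model configuration."""


class InsufficientDataError(AioCnnError):
    """Too little data to compute a diagnostic."""
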