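"""Exception hierarchy.

All package errors derive from :class:`FollipulseError` so callers can
catch analysis failures without masking programming errors.
"""


class FollipulseError(Exception):
    """Base class for all follipulse errors."""


class SpecValidationError(FollipulseError, ValueError):
    """A generator or pipeline specification field is invalid.

    Parameters
    ----------
    field : str
        Name of the offending field.
    message : str
        Human-readable description of the violation.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InputError(FollipulseError, ValueError):
    """Input data violates an operation's precondition."""


class GeometryError(FollipulseError):
    """A mask or outline is degenerate (empty, disconnected, sub-resolution)."""


class SegmentationError(FollipulseError):
    """Segmentation failed; carries diagnostics in the message."""


class InsufficientCellsError(FollipulseError):
    """Fewer analyzable cells than the configured floor (follicle excluded)."""


class InsufficientDataError(FollipulseError):
    """Too few records/observations to run the requested statistic."""


class LookupError_(FollipulseError, KeyError):
    """A requested label/cell id is not present."""
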