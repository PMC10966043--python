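"""Exception hierarchy shared across the pipeline stages."""


class GinspectError(Exception):
    """Base class for all package-specific errors."""


class EnviFormatError(GinspectError, ValueError):
    """An ENVI header is missing, unreadable, or has a garbled field."""


class ConsistencyError(GinspectError, ValueError):
    """Two pieces of metadata that must agree do not (e.g. wavelength
    count vs band count, mismatched curve lengths)."""


class DomainError(GinspectError, ValueError):
    """An argument is outside the domain an operation is defined on
    (wavelength outside the cube's range, empty ROI, bad band index)."""


class SegmentationError(GinspectError, RuntimeError):
    """Thresholding produced an empty sample or whiteboard region."""


class CalibrationError(GinspectError, RuntimeError):
    """White-reference statistics are unusable (empty or non-positive
    reference, or a sample column with no valid reference)."""


class ModelSpecError(GinspectError, ValueError):
    """A network specification cannot be built (non-positive input length,
    spatial dims not divisible by the pooling factor, zero channels)."""
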