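"""Exception hierarchy shared across the pipeline."""


class NoseprintError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NoseprintError, ValueError):
    """A parameter violates an operation's contract."""


class CaptureError(NoseprintError):
    """A simulated capture is unusable (e.g. warp pushed the ROI off-canvas)."""


class CohortSpecError(NoseprintError, ValueError):
    """A cohort specification is internally inconsistent."""


class ManifestError(NoseprintError):
    """A dataset manifest is unreadable or references missing files."""


class ValidationError(NoseprintError, ValueError):
    """A manifest row or image fails validation (e.g. ROI outside bounds)."""


class DegenerateInputError(NoseprintError):
    """An input carries no usable signal (e.g. constant-intensity crop)."""


class ComparabilityError(NoseprintError):
    """Two templates cannot be compared (shape or filter-bank mismatch)."""
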