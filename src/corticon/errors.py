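"""Exception hierarchy."""


class CorticonError(Exception):
    """Base class for all package errors."""


class ResolutionError(CorticonError):
    """A structure is too fine for the requested grid."""


class CalibrationError(CorticonError):
    """Density calibration could not be fitted or applied."""


class SegmentationError(CorticonError):
    """Cortical shell segmentation failed."""


class FitError(CorticonError):
    """Nonlinear model fit did not converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateModelError(CorticonError):
    """A fitted model collapsed to a degenerate configuration."""
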