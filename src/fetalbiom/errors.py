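"""Exception hierarchy for the biometry pipeline.

``NoPlaneFound`` / ``NoPocketFound`` are *not* exceptions: an examination
with a missing plane is a reportable clinical outcome, not a failure.  They
live in :mod:`fetalbiom.pipeline` as sentinel result types.
"""


class FetalbiomError(Exception):
    """Base class for all package errors."""


class MissingSpacingError(FetalbiomError):
    """No pixel-spacing metadata found (no DICOM tag, sidecar, or default)."""


class UnreadableFrameError(FetalbiomError):
    """A frame in a cine-loop could not be decoded."""

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class MaskFormatError(FetalbiomError):
    """A mask file is not a single-channel image or run-length record."""


class EmptyStructureError(FetalbiomError):
    """A geometric operation was asked to measure an empty mask."""


class DegenerateFitError(FetalbiomError):
    """Ellipse fitting failed: too few points, rank deficiency, or the
    constrained conic solution is not an ellipse."""


class AnisotropicSpacingError(FetalbiomError):
    """Row and column pixel spacings differ where an isotropic length
    (ellipse perimeter, oblique axis) must be converted to cm."""


class UnsupportedPlaneError(FetalbiomError):
    """Criterion classification requested for a plane that has none
    (the femoral plane's quality uses only zoom ratio and angle)."""


class BackendUnavailableError(FetalbiomError):
    """A named segmentation backend could not be located or loaded."""


class ConfigError(FetalbiomError):
    """Invalid configuration (e.g. all-zero score weights)."""


class DomainError(FetalbiomError):
    """A clinical formula received an out-of-domain input."""


class PhantomSpecError(FetalbiomError):
    """A phantom specification is internally inconsistent (structure out of
    bounds, overlapping pockets, bad best-frame index)."""


class SerializationError(FetalbiomError):
    """A report cannot be serialized (e.g. NaN measurement)."""
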