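"""Exception taxonomy for the pipeline.

Every stage signals a named error so that failures propagate with the stage
and reason attached; QC rejections are *not* errors (they return reasons).
"""


class EchosegError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(EchosegError):
    """Requested geometry is impossible (chamber outside sector, epi <= endo...)."""


class UndersampledError(EchosegError):
    """Cine cannot resolve the cardiac cycle (< 4 frames/cycle or < 1 cycle)."""


class NoROIError(EchosegError):
    """No ultrasound fan could be located in the raw image."""


class MissingSpacingError(EchosegError):
    """Pixel spacing unknown and not recoverable from metadata."""


class BadRangeError(EchosegError):
    """Empty or inverted parameter range."""


class DegenerateMaskError(EchosegError):
    """A morphological operation annihilated the mask, or a mask is too small."""


class UnassignableError(EchosegError):
    """Chamber components cannot be reassigned to anatomical labels."""


class InvalidInputError(EchosegError):
    """Inputs violate a structural precondition (e.g. overlapping masks)."""


class EmptyMaskError(EchosegError):
    """Shape descriptors requested on an empty mask."""


class UnconfiguredChamberError(EchosegError):
    """A chamber is present but the QC config has no rule for it."""


class UnconfiguredMeasureError(EchosegError):
    """A measurement has no threshold row (or required BSA is missing)."""


class ShapeError(EchosegError):
    """Array shape mismatch between paired grids."""


class ModelError(EchosegError):
    """Segmenter is untrained or incompatible with the input."""


class NoElbowError(EchosegError):
    """Loss curve is constant or linear: no curvature maximum exists."""


class EmptyTrainSetError(EchosegError):
    """No QC-passed labels available to train on."""


class StageStarvedError(EchosegError):
    """A pipeline stage produced zero QC-passed labels."""


class EmptyTraceError(EchosegError):
    """Area trace requested for a clip with no frames."""


class FitFailureError(EchosegError):
    """Sinusoid fit degenerated (constant trace / near-zero amplitude)."""


class ManualSelectionRequiredError(EchosegError):
    """All sinusoid fits failed; ED/ES frames must be chosen manually."""


class DegenerateError(EchosegError):
    """Degenerate numerical input (zero variance, mask too small for an axis...)."""


class InvertedPhasesError(EchosegError):
    """End-systolic volume exceeds end-diastolic volume."""


class UndefinedKappaError(EchosegError):
    """Cohen's kappa undefined: both raters are constant (chance agreement = 1)."""
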