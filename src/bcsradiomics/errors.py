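"""Exception types shared across the pipeline."""


class BcsRadiomicsError(Exception):
    """Base class for all package errors."""


class EmptyMaskError(BcsRadiomicsError):
    """Raised when an operation requires a nonempty ROI mask."""


class DegenerateMaskError(BcsRadiomicsError):
    """Raised when a mask is too flat for 3D geometry (coplanar/collinear voxels)."""


class LesionBoundsError(BcsRadiomicsError):
    """Raised when a simulated lesion would not fit inside the voxel grid."""


class ConstantFeatureError(BcsRadiomicsError):
    """Raised when a statistic is undefined because a feature vector is constant."""


class ValidationError(BcsRadiomicsError):
    """Raised on invalid configuration or input tables."""
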