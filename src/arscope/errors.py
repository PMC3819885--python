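"""Exception hierarchy shared across the toolkit."""


class ArscopeError(Exception):
    """Base class for all arscope errors."""


class InsufficientViewsError(ArscopeError):
    """Fewer calibration views than the intrinsic solve requires."""


class SingularSystemError(ArscopeError):
    """Degenerate geometry made a linear system rank-deficient."""


class UnderdeterminedError(ArscopeError):
    """Too few correspondences for the requested estimate."""


class DegenerateGeometryError(ArscopeError):
    """Point configuration does not constrain the estimate (e.g. collinear)."""


class NonConvergenceError(ArscopeError):
    """An iterative numeric procedure failed to converge."""


class BehindCameraError(ArscopeError):
    """One or more points have non-positive depth in the camera frame."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"points behind camera at indices {self.indices}")


class GeometryError(ArscopeError):
    """No geometrically valid solution exists."""


class MarkerCapacityError(ArscopeError):
    """code_id does not fit in the marker's payload bits."""


class AmbiguousMarkerError(ArscopeError):
    """More than one marker-like quad found in a single-marker scene."""


class FramingError(ArscopeError):
    """Requested render places the marker (partly) outside the frame."""


class VolumeFormatError(ArscopeError):
    """Unreadable or unsupported image-volume file."""


class SeedOutOfRangeError(ArscopeError):
    """Region-growing seed intensity lies outside the HU window."""


class EmptyMaskError(ArscopeError):
    """Operation requires a non-empty segmentation mask."""


class SizingError(ArscopeError):
    """Synthetic object does not fit inside the requested grid."""


class UndefinedMetricError(ArscopeError):
    """A summary metric is undefined for the given inputs."""
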