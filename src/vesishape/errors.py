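"""Exception hierarchy shared across the package."""


class VesishapeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(VesishapeError, ValueError):
    """A structure / PSF / config specification violates its invariants."""


class StructureTooLargeError(VesishapeError, ValueError):
    """The structure (plus its label shell) does not fit inside the voxel grid."""


class FlatImageError(VesishapeError, ValueError):
    """The image contains no spot to fit (constant, or nothing above background)."""


class NotConvergedError(VesishapeError, RuntimeError):
    """A derived quantity was requested from a non-converged fit."""


class InsufficientBackgroundError(VesishapeError, RuntimeError):
    """Background ROIs could not be placed outside the exclusion mask."""


class PackingError(VesishapeError, RuntimeError):
    """Spots could not be placed with the requested minimum separation."""


class ShapeMismatchError(VesishapeError, ValueError):
    """Images that must share shape / pixel size do not."""


class ZeroVarianceError(VesishapeError, ValueError):
    """Pearson correlation requested on a channel with zero variance."""


class ZeroBaselineError(VesishapeError, ValueError):
    """Fold increase requested with a zero baseline intensity."""


class DegenerateBleachError(VesishapeError, ValueError):
    """Recovery percent requested with pre-bleach == post-bleach intensity."""
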