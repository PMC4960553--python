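"""Exception hierarchy for the mrci pipeline.

Each validation failure gets its own class so callers (and the CLI) can
distinguish bad inputs from bugs.
"""


class MrciError(Exception):
    """Base class for all mrci errors."""


class GridMismatchError(MrciError):
    """Volumes in one subject do not share shape/affine."""


class NonVolumeError(MrciError):
    """An input image is not a 3D scalar volume."""


class EmptyMaskError(MrciError):
    """The brain mask contains no voxels."""


class MaskContainmentError(MrciError):
    """The tumor ROI is not contained in the brain mask."""


class DegenerateChannelError(MrciError):
    """A channel has zero variance within the brain mask."""


class EmptySampleError(MrciError):
    """No sampling-lattice point falls inside the brain mask."""


class ChannelOrderError(MrciError):
    """Feature matrices with incompatible channel order were combined."""


class EmptyInputError(MrciError):
    """An operation received an empty collection."""


class DimensionMismatchError(MrciError):
    """Feature dimension does not match the codebook."""


class ClusteringError(MrciError):
    """Invalid clustering request (e.g. K exceeds distinct units)."""


class LatticeMismatchError(MrciError):
    """Codebook and labeling do not share the same SOM lattice."""


class EmptyRoiError(MrciError):
    """The ROI mask selects no voxels."""


class GradeError(MrciError):
    """A grade group required by an operation is empty or invalid."""


class FoldError(MrciError):
    """Stratified cross-validation folds could not be constructed."""
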