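"""Named failure types raised across the package.

Every precondition violation maps to a distinct exception class so callers
(and the CLI) can tell usage errors apart from computation failures.
"""


class NiftimarkError(Exception):
    """Base class for all package-specific failures."""


class MalformedNiftiError(NiftimarkError):
    """File exists but is not a parseable NIfTI-1 image."""


class NonNumericVoxelError(NiftimarkError):
    """Voxel dtype is not a plain numeric type (e.g. RGB-packed)."""


class VoxelRangeError(NiftimarkError):
    """Requested output dtype cannot represent the voxel value range."""


class SliceRefError(NiftimarkError):
    """Slice axis/index outside the volume, or non-square without crop/pad."""


class DegenerateSliceError(NiftimarkError):
    """Constant slice where a non-degenerate one is required."""


class ShapeMismatchError(NiftimarkError):
    """Array shapes inconsistent with the operation's contract."""


class BasisMismatchError(NiftimarkError):
    """Sub-band set was produced with a different Slantlet basis."""


class KeyRejectedError(NiftimarkError):
    """Scramble key induces a non-bijective position map."""


class WrongKeyError(NiftimarkError):
    """Key fingerprint does not match the one used at embedding time."""


class ZeroEnergyWatermarkError(NiftimarkError):
    """Watermark with zero sum of squares cannot drive calibration."""


class EPROversizeError(NiftimarkError):
    """Serialized patient record exceeds the header-extension capacity."""
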