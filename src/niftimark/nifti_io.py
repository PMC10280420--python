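"""NIfTI-1 carrier I/O: volume records, slice <-> gray-scale conversion and
patient-record (EPR) attachment.

File parsing and writing are delegated to nibabel; this module owns the
watermarking-specific contracts:

* a :class:`VolumeRecord` always holds exactly 3 spatial dimensions (a 4-D
  input is reduced to its first volume and the reduction is recorded in
  ``header_meta``);
* slice <-> gray conversion is an exact inverse pair — the linear min-max
  rescale to [0, 255] stores its endpoints so ``put_gray_slice`` can invert
  it bit-faithfully (to float round-off);
* watermarked volumes default to float32 output so embedding perturbations
  are not quantized away; int16 output demands an explicit allow-clip flag
  when the value range does not fit;
* the EPR travels as a NIfTI "comment" header extension and, on write, as a
  plain-text JSON sidecar ``<file>.epr.json``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import (DegenerateSliceError, EPROversizeError,
                     MalformedNiftiError, NonNumericVoxelError,
                     ShapeMismatchError, SliceRefError, VoxelRangeError)

__all__ = ["VolumeRecord", "SliceRef", "GraySlice", "EPRRecord",
           "read_nifti", "write_nifti", "get_gray_slice", "put_gray_slice",
           "attach_epr", "detach_epr", "volume_from_array"]

_EPR_ECODE = 6          # NIfTI "comment" extension code
_EPR_MARKER = "niftimark_epr"
_EPR_MAX_BYTES = 1 << 20


@dataclass
class SliceRef:
    """Axis (0/1/2) and 0-based index of the slice to watermark."""
    axis: int
    index: int

    def __post_init__(self):
        if self.axis not in (0, 1, 2):
            raise SliceRefError(f"axis must be 0, 1 or 2, got {self.axis}")
        if self.index < 0:
            raise SliceRefError(f"index must be >= 0, got {self.index}")


@dataclass
class GraySlice:
    """Square slice on the [0, 255] scale with its inverse-rescale params."""
    pixels: np.ndarray
    rescale_lo: float
    rescale_hi: float
    side: int
    degenerate: bool = False


@dataclass
class EPRRecord:
    """Electronic patient record: free-form text fields."""
    fields: dict

    def to_json(self) -> str:
        return json.dumps({_EPR_MARKER: self.fields}, sort_keys=True,
                          separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "EPRRecord":
        data = json.loads(text)
        if _EPR_MARKER not in data:
            raise ValueError("not a niftimark EPR payload")
        return cls(fields=data[_EPR_MARKER])


@dataclass
class VolumeRecord:
    """3-D voxel array plus NIfTI header metadata and orientation affine."""
    voxels: np.ndarray
    header_meta: dict
    orientation: np.ndarray
    source_path: str = ""
    nifti_header: nib.Nifti1Header = field(default=None, repr=False)

    def __post_init__(self):
        if self.nifti_header is None:
            self.nifti_header = nib.Nifti1Header()
        if self.voxels.ndim != 3:
            raise ShapeMismatchError(
                f"voxels must be 3-D, got shape {self.voxels.shape}")

    def set_header_field(self, key: str, value):
        self.nifti_header[key] = value
        self.header_meta[key] = self.nifti_header[key]

    def copy(self) -> "VolumeRecord":
        return VolumeRecord(voxels=self.voxels.copy(),
                            header_meta=dict(self.header_meta),
                            orientation=self.orientation.copy(),
                            source_path=self.source_path,
                            nifti_header=self.nifti_header.copy())


def _meta_from_header(header) -> dict:
    return {k: header[k] for k in header.keys()}


def volume_from_array(vox, voxel_size_mm: float = 1.0,
                      description: str = "") -> VolumeRecord:
    """Wrap a 3-D array as a VolumeRecord with an isotropic-voxel header."""
    vox = np.asarray(vox, dtype=float)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    header = nib.Nifti1Header()
    header.set_data_shape(vox.shape)
    header.set_zooms((voxel_size_mm,) * 3)
    header.set_data_dtype(np.float32)
    if description:
        header["descrip"] = description.encode()[:79]
    return VolumeRecord(voxels=vox, header_meta=_meta_from_header(header),
                        orientation=affine, nifti_header=header)


def read_nifti(path) -> VolumeRecord:
    """Load a .nii/.nii.gz file into a VolumeRecord."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        dtype = img.get_data_dtype()
        if dtype.fields is not None:
            raise NonNumericVoxelError(
                f"voxel dtype {dtype} is not a plain numeric type")
        data = np.asanyarray(img.dataobj).astype(float)
    except NonNumericVoxelError:
        raise
    except Exception as exc:
        raise MalformedNiftiError(f"cannot parse {path!r}: {exc}") from exc
    meta = _meta_from_header(img.header)
    if data.ndim == 4:
        meta["reduced_from_4d"] = str(data.shape)
        data = data[..., 0]
    if data.ndim != 3:
        raise MalformedNiftiError(
            f"expected 3-D or 4-D voxel data, got shape {data.shape}")
    return VolumeRecord(voxels=data, header_meta=meta,
                        orientation=np.asarray(img.affine, dtype=float),
                        source_path=path, nifti_header=img.header.copy())


def write_nifti(vol: VolumeRecord, path, dtype: str = "float32",
                allow_clip: bool = False) -> str:
    """Write the record as NIfTI-1.

    float32 is the default so embedding perturbations are not quantized
    away by integer storage; float64 keeps the watermarked voxels
    bit-exact (useful when the extraction side must reproduce the
    embedding-time floats); int16 quantizes and demands ``allow_clip``
    when the value range does not fit.
    """
    path = os.fspath(path)
    if dtype not in ("int16", "float32", "float64"):
        raise ValueError(
            f"dtype must be 'int16', 'float32' or 'float64', got {dtype!r}")
    data = vol.voxels
    if dtype == "int16":
        lo, hi = float(data.min()), float(data.max())
        if (lo < -32768 or hi > 32767) and not allow_clip:
            raise VoxelRangeError(
                f"value range [{lo:g}, {hi:g}] does not fit int16; "
                "pass allow_clip=True to quantize anyway")
        data = np.clip(np.round(data), -32768, 32767).astype(np.int16)
    elif dtype == "float32":
        data = data.astype(np.float32)
    else:
        data = data.astype(np.float64)
    header = vol.nifti_header.copy()
    header.set_data_dtype(data.dtype)
    img = nib.Nifti1Image(data, vol.orientation, header=header)
    nib.save(img, path)
    epr = detach_epr(vol)
    if epr is not None:
        with open(path + ".epr.json", "w") as fh:
            fh.write(epr.to_json())
    return path


def _pow2(n: int) -> bool:
    return n >= 2 and (n & (n - 1)) == 0


def _extract_plane(vol: VolumeRecord, ref: SliceRef) -> np.ndarray:
    if ref.index >= vol.voxels.shape[ref.axis]:
        raise SliceRefError(
            f"index {ref.index} out of range for axis {ref.axis} "
            f"(extent {vol.voxels.shape[ref.axis]})")
    return np.take(vol.voxels, ref.index, axis=ref.axis)


def get_gray_slice(vol: VolumeRecord, ref: SliceRef, crop_pad: bool = False,
                   rescale: tuple | None = None) -> GraySlice:
    """Pull one slice and rescale it linearly onto [0, 255].

    ``rescale=(lo, hi)`` overrides the slice's own min/max — used at
    extraction time so the watermarked slice is mapped with the same
    endpoints recorded at embedding time.
    """
    plane = _extract_plane(vol, ref).astype(float)
    if plane.shape[0] != plane.shape[1] or not _pow2(plane.shape[0]):
        if not crop_pad:
            raise SliceRefError(
                f"slice shape {plane.shape} is not a power-of-two square; "
                "pass crop_pad=True for a centered crop")
        side = 1 << (min(plane.shape).bit_length() - 1)
        r0 = (plane.shape[0] - side) // 2
        c0 = (plane.shape[1] - side) // 2
        plane = plane[r0:r0 + side, c0:c0 + side]
    if rescale is not None:
        lo, hi = float(rescale[0]), float(rescale[1])
    else:
        lo, hi = float(plane.min()), float(plane.max())
    if hi <= lo:
        return GraySlice(pixels=np.zeros_like(plane), rescale_lo=lo,
                         rescale_hi=lo, side=plane.shape[0], degenerate=True)
    pixels = 255.0 * (plane - lo) / (hi - lo)
    return GraySlice(pixels=pixels, rescale_lo=lo, rescale_hi=hi,
                     side=plane.shape[0], degenerate=False)


def put_gray_slice(vol: VolumeRecord, ref: SliceRef,
                   gs: GraySlice) -> VolumeRecord:
    """Inverse-rescale a GraySlice and swap it into a copy of the volume."""
    out = vol.copy()
    plane = _extract_plane(out, ref)
    if gs.pixels.shape != plane.shape:
        raise ShapeMismatchError(
            f"gray slice shape {gs.pixels.shape} != slice shape {plane.shape}")
    if gs.degenerate:
        restored = np.full_like(gs.pixels, gs.rescale_lo)
    else:
        restored = gs.rescale_lo + (gs.rescale_hi - gs.rescale_lo) * \
            gs.pixels / 255.0
    idx = [slice(None)] * 3
    idx[ref.axis] = ref.index
    out.voxels[tuple(idx)] = restored
    return out


def attach_epr(vol: VolumeRecord, epr: EPRRecord) -> VolumeRecord:
    """Store the EPR as a 'comment' header extension on a volume copy."""
    payload = epr.to_json().encode()
    if len(payload) > _EPR_MAX_BYTES:
        raise EPROversizeError(
            f"serialized EPR is {len(payload)} bytes "
            f"(limit {_EPR_MAX_BYTES})")
    out = vol.copy()
    out.nifti_header.extensions.append(
        nib.nifti1.Nifti1Extension(_EPR_ECODE, payload))
    return out


def detach_epr(vol: VolumeRecord) -> EPRRecord | None:
    """Recover an attached EPR, or None if the volume carries none."""
    for ext in vol.nifti_header.extensions:
        if ext.get_code() != _EPR_ECODE:
            continue
        content = ext.get_content()
        if isinstance(content, bytes):
            content = content.rstrip(b"\x00").decode("utf-8", "ignore")
        try:
            return EPRRecord.from_json(content)
        except (ValueError, json.JSONDecodeError):
            continue
    return None
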