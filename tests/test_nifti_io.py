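"""Carrier I/O: file round trips, slice <-> gray inversion, EPR transport."""

import numpy as np
import pytest

import niftimark as nm
from niftimark.errors import (MalformedNiftiError, ShapeMismatchError,
                              SliceRefError, VoxelRangeError)


@pytest.fixture
def vol():
    return nm.make_phantom_volume(64, 3, seed=11)


def test_write_read_round_trip_float32_bit_exact(vol, tmp_path):
    p = nm.write_nifti(vol, tmp_path / "v.nii.gz")
    back = nm.read_nifti(p)
    # phantom voxels are float32-representable, so the payload survives
    np.testing.assert_array_equal(back.voxels, vol.voxels)
    assert back.voxels.ndim == 3
    # write -> read -> write: byte-identical voxel payload
    p2 = nm.write_nifti(back, tmp_path / "v2.nii")
    np.testing.assert_array_equal(nm.read_nifti(p2).voxels, vol.voxels)


def test_4d_input_reduced_to_first_volume(tmp_path):
    import nibabel as nib
    vol3 = nm.make_phantom_volume(32, 2, seed=3)
    four = np.stack([vol3.voxels, vol3.voxels + 1.0], axis=-1)
    nib.save(nib.Nifti1Image(four.astype(np.float32), np.eye(4)),
             tmp_path / "v4.nii")
    rec = nm.read_nifti(tmp_path / "v4.nii")
    assert rec.voxels.shape == (32, 32, 2)
    np.testing.assert_allclose(rec.voxels, vol3.voxels, atol=1e-4)
    assert "reduced_from_4d" in rec.header_meta


def test_missing_and_truncated_files(tmp_path, vol):
    with pytest.raises(FileNotFoundError):
        nm.read_nifti(tmp_path / "nope.nii")
    p = nm.write_nifti(vol, tmp_path / "t.nii")
    with open(p, "rb") as fh:
        head = fh.read(100)
    with open(tmp_path / "trunc.nii", "wb") as fh:
        fh.write(head)
    with pytest.raises(MalformedNiftiError):
        nm.read_nifti(tmp_path / "trunc.nii")


def test_int16_write_requires_allow_clip_for_wide_range(vol, tmp_path):
    wide = vol.copy()
    wide.voxels[0, 0, 0] = 1e6
    with pytest.raises(VoxelRangeError):
        nm.write_nifti(wide, tmp_path / "w.nii", dtype="int16")
    p = nm.write_nifti(wide, tmp_path / "w.nii", dtype="int16",
                       allow_clip=True)
    assert nm.read_nifti(p).voxels.max() == 32767
    with pytest.raises(ValueError):
        nm.write_nifti(vol, tmp_path / "w8.nii", dtype="uint8")


def test_descrip_header_field_survives_round_trip(vol, tmp_path):
    vol.set_header_field("descrip", b"marker-xyz")
    p = nm.write_nifti(vol, tmp_path / "d.nii")
    back = nm.read_nifti(p)
    assert b"marker-xyz" in bytes(back.header_meta["descrip"])


def test_gray_slice_rescale_endpoints(vol):
    ref = nm.SliceRef(axis=2, index=1)
    vol.voxels[:, :, 1] = np.linspace(-1000, 3000,
                                      64 * 64).reshape(64, 64)
    gs = nm.get_gray_slice(vol, ref)
    assert gs.pixels.min() == 0.0
    assert gs.pixels.max() == 255.0
    assert (gs.rescale_lo, gs.rescale_hi) == (-1000.0, 3000.0)
    assert not gs.degenerate


def test_constant_slice_flagged_degenerate(vol):
    vol.voxels[:, :, 0] = 42.0
    gs = nm.get_gray_slice(vol, nm.SliceRef(axis=2, index=0))
    assert gs.degenerate
    assert np.abs(gs.pixels).max() == 0.0


def test_get_put_gray_slice_is_inverse_pair():
    cube = nm.make_phantom_volume(32, 32, seed=13)   # cubic: any axis works
    for ref in (nm.SliceRef(axis=0, index=2), nm.SliceRef(axis=1, index=30),
                nm.SliceRef(axis=2, index=7)):
        gs = nm.get_gray_slice(cube, ref)
        back = nm.put_gray_slice(cube, ref, gs)
        assert np.abs(back.voxels - cube.voxels).max() <= \
            1e-10 * max(1.0, np.abs(cube.voxels).max())


def test_put_gray_slice_touches_only_referenced_slice(vol):
    ref = nm.SliceRef(axis=2, index=0)
    gs = nm.get_gray_slice(vol, ref)
    gs.pixels = gs.pixels + 5.0
    out = nm.put_gray_slice(vol, ref, gs)
    assert np.array_equal(out.voxels[:, :, 1:], vol.voxels[:, :, 1:])
    assert not np.array_equal(out.voxels[:, :, 0], vol.voxels[:, :, 0])


def test_slice_ref_validation(vol):
    with pytest.raises(SliceRefError):
        nm.get_gray_slice(vol, nm.SliceRef(axis=2, index=99))
    with pytest.raises(SliceRefError):
        nm.SliceRef(axis=5, index=0)
    gs = nm.get_gray_slice(vol, nm.SliceRef(axis=2, index=0))
    gs.pixels = gs.pixels[:32, :32]
    with pytest.raises(ShapeMismatchError):
        nm.put_gray_slice(vol, nm.SliceRef(axis=2, index=0), gs)


def test_non_square_slice_needs_crop_pad_flag():
    rec = nm.volume_from_array(np.zeros((64, 48, 2)) +
                               np.arange(48)[None, :, None])
    ref = nm.SliceRef(axis=2, index=0)
    with pytest.raises(SliceRefError):
        nm.get_gray_slice(rec, ref)
    gs = nm.get_gray_slice(rec, ref, crop_pad=True)
    assert gs.side == 32
    assert gs.pixels.shape == (32, 32)


def test_epr_attach_detach_round_trip(vol):
    epr = nm.EPRRecord({"id": "P001", "name": "test", "notes": "n/a"})
    out = nm.attach_epr(vol, epr)
    assert nm.detach_epr(out).fields == epr.fields
    assert nm.detach_epr(vol) is None   # original untouched, and absence
    # of an EPR is an explicit None, not a failure


def test_epr_file_round_trip(vol, tmp_path):
    epr = nm.EPRRecord({"id": "P002", "name": "x"})
    out = nm.attach_epr(vol, epr)
    p = nm.write_nifti(out, tmp_path / "e.nii.gz")
    assert nm.detach_epr(nm.read_nifti(p)).fields == epr.fields
    assert (tmp_path / "e.nii.gz.epr.json").exists()


def test_oversize_epr_rejected(vol):
    from niftimark.errors import EPROversizeError
    with pytest.raises(EPROversizeError):
        nm.attach_epr(vol, nm.EPRRecord({"blob": "x" * (1 << 21)}))
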