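"""Embedding/extraction pipelines: closed-form imperceptibility, exact
attack-free recovery, strength calibration, volume plumbing."""

import numpy as np
import pytest

import niftimark as nm
from niftimark.errors import (DegenerateSliceError, ShapeMismatchError,
                              WrongKeyError)


def gray(pixels):
    return nm.GraySlice(pixels=pixels, rescale_lo=0.0, rescale_hi=255.0,
                        side=pixels.shape[0])


def test_mu_zero_is_exact_identity(phantom512, logo64, key64):
    wm, _ = nm.embed_slice(phantom512, logo64,
                           nm.EmbedConfig(mu=0.0, key=key64))
    np.testing.assert_array_equal(wm.pixels, phantom512.pixels)


@pytest.mark.parametrize("N", [64, 128, 512])
def test_closed_form_mse_and_psnr(N, key64):
    T = min(64, N // 4)
    key = key64 if T == 64 else nm.default_key(T)
    w = nm.make_watermark(T)
    gs = gray(nm.make_phantom_slice(N, seed=5))
    mu = 0.01
    wm, _ = nm.embed_slice(gs, w, nm.EmbedConfig(mu=mu, key=key))
    expected_mse = mu ** 2 * np.sum(w ** 2) / N ** 2
    assert nm.mse(gs.pixels, wm.pixels) == pytest.approx(expected_mse,
                                                         rel=1e-9)
    expected_psnr = 10 * np.log10(255.0 ** 2 * N ** 2 /
                                  (mu ** 2 * np.sum(w ** 2)))
    assert nm.psnr(gs.pixels, wm.pixels) == pytest.approx(expected_psnr,
                                                          abs=1e-3)


@pytest.mark.parametrize("mu", [1e-4, 0.01, 1.0])
def test_attack_free_extraction_is_exact(phantom512, logo64, key64, mu):
    cfg = nm.EmbedConfig(mu=mu, key=key64)
    wm, rec = nm.embed_slice(phantom512, logo64, cfg)
    out = nm.extract_slice(wm, phantom512, cfg,
                           expected_fingerprint=rec.key_fingerprint)
    assert np.abs(out - logo64).max() < 1e-6
    assert nm.nc(logo64, out) == pytest.approx(1.0, abs=1e-9)
    assert nm.ssim(logo64, out) == pytest.approx(1.0, abs=1e-9)


def test_extracting_from_unwatermarked_slice_gives_zeros(phantom512, key64):
    cfg = nm.EmbedConfig(mu=0.01, key=key64)
    out = nm.extract_slice(phantom512, phantom512, cfg)
    assert np.abs(out).max() < 1e-6


def test_redecompose_mode_runs_but_is_inexact(phantom512, logo64, key64):
    """The literal re-decomposition route: a fresh Hessenberg factorization
    of the perturbed LL does not reproduce H + mu*W, so recovery is
    degraded relative to the similarity route."""
    cfg = nm.EmbedConfig(mu=0.01, key=key64, extraction_mode="redecompose")
    wm, _ = nm.embed_slice(phantom512, logo64, cfg)
    out = nm.extract_slice(wm, phantom512, cfg)
    assert out.shape == (64, 64)
    assert np.all(np.isfinite(out))
    sim = nm.extract_slice(wm, phantom512,
                           nm.EmbedConfig(mu=0.01, key=key64))
    assert np.abs(sim - logo64).max() < np.abs(out - logo64).max()


def test_embedded_perturbation_keeps_h_hessenberg(phantom512, logo64, key64):
    basis = nm.build_slantlet_matrix(512, 1)
    cfg = nm.EmbedConfig(mu=0.5, key=key64)
    wm, rec = nm.embed_slice(phantom512, logo64, cfg)
    sb = nm.slt_forward_2d(wm.pixels, basis)
    fac0 = nm.hessenberg_decompose(
        nm.slt_forward_2d(phantom512.pixels, basis).LL)
    h_star = nm.similarity_transform(sb.LL, fac0.Q)
    assert np.abs(np.tril(h_star, -2)).max() < 1e-6


def test_placement_must_be_strictly_upper(phantom512, logo64, key64):
    with pytest.raises(ShapeMismatchError):
        nm.embed_slice(phantom512, logo64,
                       nm.EmbedConfig(mu=0.01, key=key64,
                                      placement=(100, 120)))
    with pytest.raises(ShapeMismatchError):
        nm.embed_slice(phantom512, logo64,
                       nm.EmbedConfig(mu=0.01, key=key64,
                                      placement=(0, 250)))


def test_watermark_too_large_rejected(key64):
    gs = gray(nm.make_phantom_slice(128, seed=5))
    with pytest.raises(ShapeMismatchError):
        nm.embed_slice(gs, nm.make_watermark(64),
                       nm.EmbedConfig(mu=0.01, key=key64))


def test_degenerate_slice_rejected(logo64, key64):
    gs = nm.GraySlice(pixels=np.zeros((512, 512)), rescale_lo=0.0,
                      rescale_hi=0.0, side=512, degenerate=True)
    with pytest.raises(DegenerateSliceError):
        nm.embed_slice(gs, logo64, nm.EmbedConfig(mu=0.01, key=key64))


def test_calibrate_mu_hits_target_psnr(phantom512, logo64, key64):
    mu = nm.calibrate_mu(logo64, 512, 60.5)
    wm, _ = nm.embed_slice(phantom512, logo64,
                           nm.EmbedConfig(mu=mu, key=key64))
    assert nm.psnr(phantom512.pixels, wm.pixels) == pytest.approx(60.5,
                                                                  abs=0.01)


def test_calibrate_mu_formula_properties(logo64):
    from niftimark.errors import ZeroEnergyWatermarkError
    mu1 = nm.calibrate_mu(logo64, 512, 60.0)
    mu2 = nm.calibrate_mu(logo64, 512, 60.0 + 20 * np.log10(2.0))
    assert mu2 == pytest.approx(mu1 / 2.0, rel=1e-12)
    with pytest.raises(ZeroEnergyWatermarkError):
        nm.calibrate_mu(np.zeros((64, 64)), 512, 60.0)


def test_embed_volume_touches_only_target_slice(logo64, key64):
    vol = nm.make_phantom_volume(512, 3, seed=2)
    cfg = nm.EmbedConfig(mu=0.01, key=key64,
                         slice=nm.SliceRef(axis=2, index=1))
    out, rec = nm.embed_volume(vol, logo64, cfg,
                               epr=nm.EPRRecord({"id": "P1"}))
    assert np.array_equal(out.voxels[:, :, 0], vol.voxels[:, :, 0])
    assert np.array_equal(out.voxels[:, :, 2], vol.voxels[:, :, 2])
    assert not np.array_equal(out.voxels[:, :, 1], vol.voxels[:, :, 1])
    assert nm.detach_epr(out).fields == {"id": "P1"}


def test_volume_file_round_trip_extraction(logo64, key64, tmp_path):
    vol = nm.make_phantom_volume(512, 2, seed=2)
    cfg = nm.EmbedConfig(mu=0.01, key=key64,
                         slice=nm.SliceRef(axis=2, index=0))
    wm_vol, rec = nm.embed_volume(vol, logo64, cfg)
    rec2 = nm.EmbedRecord.from_json(rec.to_json())

    # lossless float64 files: extraction is exact
    p_wm = nm.write_nifti(wm_vol, tmp_path / "wm.nii.gz", dtype="float64")
    p_or = nm.write_nifti(vol, tmp_path / "orig.nii.gz", dtype="float64")
    out = nm.extract_volume(nm.read_nifti(p_wm), nm.read_nifti(p_or),
                            rec2, key64)
    assert nm.nc(logo64, out) == pytest.approx(1.0, abs=1e-9)

    # default float32 files: watermarked voxels are quantized, recovery
    # degrades only by that quantization noise
    p_wm32 = nm.write_nifti(wm_vol, tmp_path / "wm32.nii.gz")
    p_or32 = nm.write_nifti(vol, tmp_path / "orig32.nii.gz")
    out32 = nm.extract_volume(nm.read_nifti(p_wm32), nm.read_nifti(p_or32),
                              rec2, key64)
    assert nm.nc(logo64, out32) == pytest.approx(1.0, abs=1e-6)


def test_extract_volume_guards(logo64, key64):
    vol = nm.make_phantom_volume(128, 2, seed=2)
    small_key = nm.default_key(32)
    w32 = nm.make_watermark(32)
    cfg = nm.EmbedConfig(mu=0.01, key=small_key)
    wm_vol, rec = nm.embed_volume(vol, w32, cfg)
    other = nm.make_phantom_volume(64, 2, seed=2)
    with pytest.raises(ShapeMismatchError):
        nm.extract_volume(wm_vol, other, rec, small_key)
    wrong = nm.validate_key([[2, 1], [1, 1]], 1, 5, 32)
    with pytest.raises(WrongKeyError):
        nm.extract_volume(wm_vol, vol, rec, wrong)


def test_wrong_fingerprint_fails_at_unscramble(phantom512, logo64, key64):
    cfg = nm.EmbedConfig(mu=0.01, key=key64)
    wm, rec = nm.embed_slice(phantom512, logo64, cfg)
    with pytest.raises(WrongKeyError):
        nm.extract_slice(wm, phantom512, cfg,
                         expected_fingerprint="not-the-right-key")
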