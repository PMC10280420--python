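"""End-to-end watermark embedding and non-blind extraction.

Embedding pipeline over an N x N gray slice (N a power of two):

1. one-level 2-D Slantlet analysis -> LL, LH, HL, HH sub-bands;
2. Householder Hessenberg decomposition of LL = Q . H . Q^T;
3. affine scrambling of the T x T watermark;
4. the scrambled values are placed in a T x T block of the strictly
   upper-triangular part of H (default: top-right corner) and added with
   strength mu:  H' = H + mu . P;
5. LL' = Q . H' . Q^T, then inverse Slantlet with the untouched LH/HL/HH.

Because both the Slantlet matrix and Q are orthogonal, the spatial-domain
perturbation has Frobenius norm exactly mu ||W||_F, which gives the closed
forms  MSE = mu^2 sum(W^2) / N^2  and  PSNR = 10 log10(255^2 N^2 /
(mu^2 sum(W^2)));  ``calibrate_mu`` inverts the latter to hit a target PSNR
exactly in the float pipeline.

Extraction is non-blind (requires the original slice).  The default
``similarity`` mode reuses the embedding-side Q: H* = Q^T . LL* . Q, so the
attack-free round trip is exact.  The literal ``redecompose`` mode runs a
fresh Hessenberg decomposition on LL* instead; it is kept for fidelity
experiments but is not an exact inverse, because the reflectors drift once
the perturbation mixes into the sub-diagonal structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nifti_io
from .errors import (DegenerateSliceError, ShapeMismatchError, WrongKeyError,
                     ZeroEnergyWatermarkError)
from .hessenberg import hessenberg_decompose, hessenberg_reconstruct, \
    similarity_transform
from .nifti_io import GraySlice, SliceRef, VolumeRecord, EPRRecord
from .scramble import ScrambleKey, ScrambledWatermark, scramble, unscramble
from .slantlet import build_slantlet_matrix, slt_forward_2d, slt_inverse_2d

__all__ = ["EmbedConfig", "EmbedRecord", "embed_slice", "extract_slice",
           "embed_volume", "extract_volume", "calibrate_mu"]

VERSION = "0.1.0"


@dataclass
class EmbedConfig:
    """Everything the embedding pipeline needs besides the images."""
    mu: float
    key: ScrambleKey
    slice: SliceRef = field(default_factory=lambda: SliceRef(axis=2, index=0))
    placement: tuple | None = None       # (row0, col0), 0-based within H
    extraction_mode: str = "similarity"  # or "redecompose"
    scales: int = 1                      # Slantlet scales L

    def resolved_placement(self, half: int, T: int) -> tuple[int, int]:
        """Default: top-right T x T corner of the (half x half) H factor."""
        if self.placement is None:
            row0, col0 = 0, half - T
        else:
            row0, col0 = self.placement
        if row0 < 0 or col0 < 0 or row0 + T > half or col0 + T > half:
            raise ShapeMismatchError(
                f"placement block ({row0},{col0})+{T} leaves the "
                f"{half}x{half} factor")
        if col0 <= row0 + T - 1:
            raise ShapeMismatchError(
                "placement block must lie strictly above the diagonal "
                f"(need col0 > row0 + T - 1, got row0={row0}, col0={col0})")
        return row0, col0


@dataclass
class EmbedRecord:
    """Sidecar record sufficient to drive (non-blind) extraction."""
    mu: float
    key_fingerprint: str
    slice_axis: int
    slice_index: int
    placement: tuple
    watermark_side: int
    rescale_lo: float
    rescale_hi: float
    basis_n: int
    basis_scales: int
    extraction_mode: str
    coordinate_convention: str = "0-based"
    version: str = VERSION

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EmbedRecord":
        d = json.loads(text)
        d["placement"] = tuple(d["placement"])
        return cls(**d)


def _watermark_array(watermark) -> np.ndarray:
    w = np.asarray(watermark, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ShapeMismatchError(f"watermark must be square, got {w.shape}")
    return w


def calibrate_mu(watermark, N: int, target_psnr: float,
                 max_value: float = 255.0) -> float:
    """Embedding strength that yields exactly ``target_psnr`` dB on an
    N x N slice (float pipeline, closed form)."""
    w = _watermark_array(watermark)
    energy = float(np.sum(w ** 2))
    if energy == 0.0:
        raise ZeroEnergyWatermarkError("watermark has zero energy")
    return float(np.sqrt(max_value ** 2 * N ** 2 /
                         (10.0 ** (target_psnr / 10.0) * energy)))


def embed_slice(gs: GraySlice, watermark, cfg: EmbedConfig
                ) -> tuple[GraySlice, EmbedRecord]:
    """Algorithmic core: returns the watermarked slice (float, unclamped)
    and the extraction record."""
    if gs.degenerate:
        raise DegenerateSliceError("cannot embed into a constant slice")
    if cfg.mu < 0:
        raise ValueError("mu must be non-negative")
    w = _watermark_array(watermark)
    T = w.shape[0]
    N = gs.side
    if T > N // 4:
        raise ShapeMismatchError(
            f"watermark side {T} exceeds N/4 = {N // 4} for slice side {N}")
    if cfg.key.T != T:
        raise ShapeMismatchError(
            f"key grid T={cfg.key.T} != watermark side {T}")

    basis = build_slantlet_matrix(N, cfg.scales)
    sb = slt_forward_2d(gs.pixels, basis)
    fac = hessenberg_decompose(sb.LL)
    half = N // 2
    row0, col0 = cfg.resolved_placement(half, T)

    sw = scramble(w, cfg.key)
    if cfg.mu == 0.0:
        # nothing to add; keep the slice bit-identical
        wm_pixels = gs.pixels.copy()
    else:
        P = np.zeros((half, half))
        P[row0:row0 + T, col0:col0 + T] = sw.values
        H_mod = fac.H + cfg.mu * P
        sb.LL = fac.Q @ H_mod @ fac.Q.T
        wm_pixels = slt_inverse_2d(sb, basis)

    record = EmbedRecord(mu=cfg.mu, key_fingerprint=cfg.key.fingerprint,
                         slice_axis=cfg.slice.axis,
                         slice_index=cfg.slice.index,
                         placement=(row0, col0), watermark_side=T,
                         rescale_lo=gs.rescale_lo, rescale_hi=gs.rescale_hi,
                         basis_n=N, basis_scales=cfg.scales,
                         extraction_mode=cfg.extraction_mode)
    wm = GraySlice(pixels=wm_pixels, rescale_lo=gs.rescale_lo,
                   rescale_hi=gs.rescale_hi, side=N, degenerate=False)
    return wm, record


def extract_slice(wm: GraySlice, original: GraySlice, cfg: EmbedConfig,
                  expected_fingerprint: str | None = None) -> np.ndarray:
    """Non-blind extraction: W = unscramble((H* - H) / mu) block.

    If ``expected_fingerprint`` (from the embed record) is given and does
    not match ``cfg.key``, unscrambling fails with a wrong-key error rather
    than silently returning a garbled watermark.
    """
    if wm.side != original.side:
        raise ShapeMismatchError(
            f"slice sides differ: {wm.side} vs {original.side}")
    if cfg.mu <= 0:
        raise ValueError("mu must be positive for extraction")
    T = cfg.key.T
    N = original.side
    basis = build_slantlet_matrix(N, cfg.scales)
    sb_orig = slt_forward_2d(original.pixels, basis)
    sb_wm = slt_forward_2d(wm.pixels, basis)
    fac = hessenberg_decompose(sb_orig.LL)
    if cfg.extraction_mode == "similarity":
        H_star = similarity_transform(sb_wm.LL, fac.Q)
    elif cfg.extraction_mode == "redecompose":
        H_star = hessenberg_decompose(sb_wm.LL).H
    else:
        raise ValueError(f"unknown extraction mode {cfg.extraction_mode!r}")
    half = N // 2
    row0, col0 = cfg.resolved_placement(half, T)
    block = (H_star - fac.H)[row0:row0 + T, col0:col0 + T] / cfg.mu
    fingerprint = expected_fingerprint or cfg.key.fingerprint
    sw = ScrambledWatermark(values=block, key_fingerprint=fingerprint)
    return unscramble(sw, cfg.key)


def embed_volume(vol: VolumeRecord, watermark, cfg: EmbedConfig,
                 epr: EPRRecord | None = None
                 ) -> tuple[VolumeRecord, EmbedRecord]:
    """Embed into the configured slice of a volume and attach the EPR."""
    gs = nifti_io.get_gray_slice(vol, cfg.slice)
    wm_slice, record = embed_slice(gs, watermark, cfg)
    out = nifti_io.put_gray_slice(vol, cfg.slice, wm_slice)
    if epr is not None:
        out = nifti_io.attach_epr(out, epr)
    return out, record


def extract_volume(wm_vol: VolumeRecord, orig_vol: VolumeRecord,
                   record: EmbedRecord, key: ScrambleKey) -> np.ndarray:
    """Pull the recorded slice from both volumes and extract the watermark.

    Both slices are rescaled with the endpoints stored at embedding time so
    the gray-scale pipeline is reproduced exactly.
    """
    if wm_vol.voxels.shape != orig_vol.voxels.shape:
        raise ShapeMismatchError(
            f"volume shapes differ: {wm_vol.voxels.shape} vs "
            f"{orig_vol.voxels.shape}")
    if key.fingerprint != record.key_fingerprint:
        raise WrongKeyError("key fingerprint does not match embed record")
    ref = SliceRef(axis=record.slice_axis, index=record.slice_index)
    rescale = (record.rescale_lo, record.rescale_hi)
    gs_wm = nifti_io.get_gray_slice(wm_vol, ref, rescale=rescale)
    gs_orig = nifti_io.get_gray_slice(orig_vol, ref, rescale=rescale)
    cfg = EmbedConfig(mu=record.mu, key=key, slice=ref,
                      placement=record.placement,
                      extraction_mode=record.extraction_mode,
                      scales=record.basis_scales)
    return extract_slice(gs_wm, gs_orig, cfg)
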