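"""Deterministic synthetic fixtures: CT-like phantom slices/volumes and logo
watermarks.

Everything is generated from an explicit seed through numpy's PCG64
generator, so identical specs produce bit-identical arrays on any platform.
A phantom slice is a large elliptical "body" containing several seeded
internal ellipses plus a low-amplitude smooth texture, clipped to the
[0, 255] display scale — enough structure for the transform, embedding and
attack stages to behave as they would on a real axial CT slice, without any
anatomical realism.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import nifti_io

__all__ = ["make_phantom_slice", "make_watermark", "make_phantom_volume"]


def _check_pow2(n: int, name: str):
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"{name} must be a power of two >= 2, got {n}")


def _ellipse(N: int, cy, cx, ry, rx, angle) -> np.ndarray:
    yy, xx = np.mgrid[0:N, 0:N]
    y = yy - cy
    x = xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_phantom_slice(N: int, seed: int) -> np.ndarray:
    """CT-like N x N phantom on [0, 255]; bit-identical for identical args."""
    _check_pow2(N, "N")
    rng = np.random.Generator(np.random.PCG64(seed))
    img = np.zeros((N, N))
    # body
    img += 90.0 * _ellipse(N, N / 2, N / 2, 0.42 * N, 0.36 * N,
                           rng.uniform(-0.2, 0.2))
    # internal structures
    for _ in range(6):
        cy = rng.uniform(0.3, 0.7) * N
        cx = rng.uniform(0.3, 0.7) * N
        ry = rng.uniform(0.04, 0.15) * N
        rx = rng.uniform(0.04, 0.15) * N
        amp = rng.uniform(-60.0, 110.0)
        img += amp * _ellipse(N, cy, cx, ry, rx, rng.uniform(0, np.pi))
    # smooth low-amplitude texture
    tex = ndimage.gaussian_filter(rng.standard_normal((N, N)), sigma=N / 64)
    tex *= 8.0 / max(tex.std(), 1e-12)
    img += 40.0 + tex
    # float32-representable values: the phantom survives a float32 NIfTI
    # round trip bit-exactly, which non-blind extraction relies on
    return np.clip(img, 0.0, 255.0).astype(np.float32).astype(float)


def make_watermark(T: int = 64, seed: int | None = None) -> np.ndarray:
    """T x T gray watermark: built-in geometric logo, or seeded random."""
    _check_pow2(T, "T")
    if seed is not None:
        rng = np.random.Generator(np.random.PCG64(seed))
        return np.round(rng.uniform(0.0, 255.0, size=(T, T)))
    # built-in logo: concentric rings plus text-like blocks
    yy, xx = np.mgrid[0:T, 0:T]
    r = np.hypot(yy - (T - 1) / 2, xx - (T - 1) / 2)
    img = np.zeros((T, T))
    img[(r > 0.30 * T) & (r <= 0.40 * T)] = 200.0
    img[(r > 0.16 * T) & (r <= 0.24 * T)] = 120.0
    img[r <= 0.08 * T] = 255.0
    q = max(T // 8, 1)
    img[q:2 * q, q:3 * q] = 230.0          # block marks in the corners
    img[-2 * q:-q, -3 * q:-q] = 180.0
    img[q:2 * q, -2 * q:-q] = 90.0
    return img


def make_phantom_volume(N: int, n_slices: int, seed: int) -> "nifti_io.VolumeRecord":
    """Stack of correlated phantom slices wrapped as a NIfTI volume record.

    Slices share a common seeded base and differ by small seeded
    perturbations, mimicking through-plane continuity; the header reports
    1 mm isotropic voxels.
    """
    _check_pow2(N, "N")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    ss = np.random.SeedSequence(seed)
    base_seed, *slice_seeds = ss.spawn(n_slices + 1)
    base = make_phantom_slice(N, seed)
    vox = np.empty((N, N, n_slices))
    for z, child in enumerate(slice_seeds):
        rng = np.random.Generator(np.random.PCG64(child))
        bump = ndimage.gaussian_filter(rng.standard_normal((N, N)),
                                       sigma=N / 32)
        bump *= 4.0 / max(bump.std(), 1e-12)
        vox[:, :, z] = np.clip(base + bump, 0.0, 255.0)
    vox = vox.astype(np.float32).astype(float)
    return nifti_io.volume_from_array(vox, voxel_size_mm=1.0,
                                      description="niftimark phantom")
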