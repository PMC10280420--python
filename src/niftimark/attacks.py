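"""Attack catalog and the robustness bench.

Ten classical image-processing attacks are applied to the watermarked slice
before extraction, at the default settings of the benchmark they mimic:
speckle noise (variance 0.004), JPEG compression (quality 80), unsharp
sharpening (amount 0.2), histogram equalization, 3x3 average filter, motion
blur (strength 0.2 -> 3-pixel horizontal kernel), 3x3 Gaussian low-pass
filter, 3x3 median filter, additive Gaussian noise (variance 0.005) and
salt & pepper noise (density 0.003).  An optional unit-scale Poisson attack
is available but not part of the default set.

Noise variances/densities are interpreted on the unit-normalized [0, 1]
intensity scale and mapped back to [0, 255] — the convention of the toolbox
these settings come from.  Stochastic attacks are deterministic given a
seed.  Attacked pixels are clipped to [0, 255]: attacks model real-world
degradation of a display-scale image (this deliberately breaks the float
closed forms that hold for the attack-free pipeline).

``run_robustness_bench`` embeds, attacks, extracts and scores the extracted
watermark (PSNR / SSIM / NC against the original watermark) per attack,
returning a pandas DataFrame in the benchmark's column layout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import exposure

from . import metrics, nifti_io
from .errors import ShapeMismatchError
from .nifti_io import GraySlice, SliceRef, VolumeRecord
from .watermarker import EmbedConfig, embed_slice, extract_slice

__all__ = ["AttackSpec", "apply_attack", "run_robustness_bench",
           "DEFAULT_ATTACKS", "default_attack_suite"]

#: the ten default attacks with their canonical settings
DEFAULT_ATTACKS = (
    ("speckle", {"variance": 0.004}),
    ("jpeg", {"quality": 80}),
    ("sharpen", {"amount": 0.2}),
    ("hist_eq", {}),
    ("average_filter", {"size": 3}),
    ("motion_blur", {"strength": 0.2}),
    ("gaussian_lpf", {"size": 3, "sigma": 0.5}),
    ("median_filter", {"size": 3}),
    ("gaussian_noise", {"variance": 0.005}),
    ("salt_pepper", {"density": 0.003}),
)

_DEFAULT_PARAMS = {name: dict(params) for name, params in DEFAULT_ATTACKS}
_DEFAULT_PARAMS["poisson"] = {}


@dataclass
class AttackSpec:
    """Named attack plus parameters; unset params take the catalog defaults."""
    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in _DEFAULT_PARAMS:
            raise ValueError(f"unknown attack {self.name!r}; choose from "
                             f"{sorted(_DEFAULT_PARAMS)}")
        merged = dict(_DEFAULT_PARAMS[self.name])
        merged.update(self.params)
        self.params = merged


def default_attack_suite(seed: int = 0) -> list[AttackSpec]:
    return [AttackSpec(name, dict(params), seed=seed)
            for name, params in DEFAULT_ATTACKS]


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size, dtype=float) - (size - 1) / 2.0
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def _apply(pixels: np.ndarray, name: str, p: dict,
           rng: np.random.Generator) -> np.ndarray:
    unit = pixels / 255.0
    if name == "speckle":
        if p["variance"] == 0.0:
            return pixels.copy()
        out = unit + unit * rng.normal(0.0, np.sqrt(p["variance"]),
                                       size=unit.shape)
        return out * 255.0
    if name == "gaussian_noise":
        if p["variance"] == 0.0:
            return pixels.copy()
        out = unit + rng.normal(0.0, np.sqrt(p["variance"]), size=unit.shape)
        return out * 255.0
    if name == "salt_pepper":
        out = pixels.copy()
        d = float(p["density"])
        if d > 0:
            mask = rng.random(pixels.shape) < d
            salt = rng.random(pixels.shape) < 0.5
            out[mask & salt] = 255.0
            out[mask & ~salt] = 0.0
        return out
    if name == "poisson":
        # unit-scale Poisson: quantize to 255 levels, draw counts
        return rng.poisson(np.clip(unit, 0, 1) * 255.0).astype(float)
    if name == "jpeg":
        img8 = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
        buf = io.BytesIO()
        Image.fromarray(img8, mode="L").save(buf, format="JPEG",
                                             quality=int(p["quality"]))
        buf.seek(0)
        return np.asarray(Image.open(buf), dtype=float)
    if name == "sharpen":
        amount = float(p["amount"])
        if amount == 0.0:
            return pixels.copy()
        lap = ndimage.convolve(pixels, np.array([[0., 1., 0.],
                                                 [1., -4., 1.],
                                                 [0., 1., 0.]]),
                               mode="reflect")
        return pixels - amount * lap
    if name == "hist_eq":
        return exposure.equalize_hist(np.clip(pixels, 0, 255) / 255.0) * 255.0
    if name == "average_filter":
        return ndimage.uniform_filter(pixels, size=int(p["size"]),
                                      mode="reflect")
    if name == "motion_blur":
        s = float(p["strength"])
        if s == 0.0:
            return pixels.copy()
        length = max(2, round(s * 15))
        kern = np.ones((1, length)) / length
        return ndimage.convolve(pixels, kern, mode="reflect")
    if name == "gaussian_lpf":
        kern = _gaussian_kernel(int(p["size"]), float(p["sigma"]))
        return ndimage.convolve(pixels, kern, mode="reflect")
    if name == "median_filter":
        return ndimage.median_filter(pixels, size=int(p["size"]),
                                     mode="reflect")
    raise ValueError(f"unknown attack {name!r}")  # pragma: no cover


def apply_attack(gs: GraySlice, spec: AttackSpec) -> GraySlice:
    """Attack a [0, 255]-scale slice; output is clipped to the same scale."""
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    out = _apply(np.asarray(gs.pixels, dtype=float), spec.name, spec.params,
                 rng)
    out = np.clip(out, 0.0, 255.0)
    return GraySlice(pixels=out, rescale_lo=gs.rescale_lo,
                     rescale_hi=gs.rescale_hi, side=gs.side,
                     degenerate=gs.degenerate)


def run_robustness_bench(vol: VolumeRecord, watermark, cfg: EmbedConfig,
                         specs: list[AttackSpec],
                         include_no_attack: bool = True) -> pd.DataFrame:
    """Embed once, then attack / extract / score per attack spec.

    Returns a DataFrame with columns (attack, params, psnr_db, ssim, nc)
    plus the extracted watermark arrays in an ``extracted`` column.
    """
    w = np.asarray(watermark, dtype=float)
    gs = nifti_io.get_gray_slice(vol, cfg.slice)
    wm_slice, record = embed_slice(gs, w, cfg)
    rows = []
    runs = ([("none", None)] if include_no_attack else []) + \
        [(spec.name, spec) for spec in specs]
    for name, spec in runs:
        attacked = wm_slice if spec is None else apply_attack(wm_slice, spec)
        extracted = extract_slice(attacked, gs, cfg,
                                  expected_fingerprint=record.key_fingerprint)
        # the extracted watermark is reported as an 8-bit-range image:
        # clip noise excursions to the displayable [0, 255] scale before
        # scoring (attack-free extraction is unaffected to < 1e-6)
        extracted = np.clip(extracted, 0.0, 255.0)
        rows.append({
            "attack": name,
            "params": "" if spec is None else repr(spec.params),
            "psnr_db": metrics.psnr(w, extracted),
            "ssim": metrics.ssim(w, extracted),
            "nc": metrics.nc(w, extracted),
            "extracted": extracted,
        })
    return pd.DataFrame(rows)
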