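"""Image-quality and watermark-fidelity measures.

All measures operate on equal-size 2-D gray arrays on the [0, 255] scale
(``max_value`` defaults to 255).  Conventions worth noting:

* ``psnr``/``snr`` report ``float('inf')`` as an explicit sentinel when the
  error power is zero; this is never an error.
* ``nc`` uses the asymmetric normalization sum(w . w*) / sum(w^2).  It is 1
  for a perfect copy and *linear* in its second argument, so values above 1
  are possible by design; it is a watermark-recovery score, not a bounded
  correlation coefficient.
* ``q_index`` is the universal image quality index evaluated globally over
  the whole image (a single window), using population (ddof=0) moments.
* ``ssim`` is the mean local structural similarity with the standard
  11 x 11 Gaussian window (sigma = 1.5) and stabilisers p1 = (0.01 Max)^2,
  p2 = (0.03 Max)^2.  Images smaller than the window fall back to a single
  global window and the report flags it.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

from .errors import ShapeMismatchError

__all__ = ["QualityReport", "mse", "psnr", "snr", "nc", "q_index", "ssim",
           "evaluate_pair", "write_report_csv"]

#: column order used for CSV reports (imperceptibility table layout)
REPORT_COLUMNS = ("psnr_db", "snr_db", "ssim", "nc", "q_index")


def _pair(A, B):
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ShapeMismatchError(f"shapes differ: {A.shape} vs {B.shape}")
    return A, B


@dataclass
class QualityReport:
    mse: float
    psnr_db: float
    snr_db: float
    nc: float
    q_index: float
    ssim: float
    m: int
    n: int
    max_value: float = 255.0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def csv_row(self) -> list:
        return [getattr(self, c) for c in REPORT_COLUMNS]


def mse(A, B) -> float:
    """Mean squared difference."""
    A, B = _pair(A, B)
    return float(np.mean((A - B) ** 2))


def psnr(A, B, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio, 10 log10(Max^2 / MSE), in dB."""
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    e = mse(A, B)
    if e == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value ** 2 / e))


def snr(A, B) -> float:
    """Signal power over error power, 10 log10(sum A^2 / sum (A-B)^2), dB."""
    A, B = _pair(A, B)
    sig = float(np.sum(A ** 2))
    if sig == 0.0:
        raise ValueError("reference image has zero signal power")
    err = float(np.sum((A - B) ** 2))
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(sig / err))


def nc(w, w_star) -> float:
    """Normalized correlation sum(w . w*) / sum(w^2) (asymmetric)."""
    w, w_star = _pair(w, w_star)
    denom = float(np.sum(w ** 2))
    if denom == 0.0:
        raise ValueError("reference watermark has zero energy")
    return float(np.sum(w * w_star) / denom)


def q_index(x, y) -> float:
    """Universal image quality index over a single global window."""
    x, y = _pair(x, y)
    xb, yb = x.mean(), y.mean()
    sx2, sy2 = x.var(), y.var()
    if sx2 == 0.0 or sy2 == 0.0:
        raise ValueError("q_index is undefined for constant images")
    if xb == 0.0 and yb == 0.0:
        raise ValueError("q_index is undefined for zero-mean image pairs")
    sxy = float(np.mean((x - xb) * (y - yb)))
    return float(4.0 * sxy * xb * yb / ((sx2 + sy2) * (xb ** 2 + yb ** 2)))


def ssim(j, k, max_value: float = 255.0) -> float:
    """Mean local SSIM (11 x 11 Gaussian window, sigma 1.5)."""
    j, k = _pair(j, k)
    if min(j.shape) < 11:
        warnings.warn("image smaller than the 11x11 SSIM window; "
                      "falling back to one global window", stacklevel=2)
        win = min(j.shape)
        win -= 1 - win % 2  # largest odd size that fits
        return float(structural_similarity(
            j, k, win_size=win, gaussian_weights=False,
            use_sample_covariance=False, data_range=max_value))
    return float(structural_similarity(
        j, k, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=max_value))


def evaluate_pair(A, B, max_value: float = 255.0) -> QualityReport:
    """All six measures for an image pair (A = reference)."""
    A, B = _pair(A, B)
    try:
        q = q_index(A, B)
    except ValueError:
        q = float("nan")
    return QualityReport(mse=mse(A, B), psnr_db=psnr(A, B, max_value),
                         snr_db=snr(A, B), nc=nc(A, B), q_index=q,
                         ssim=ssim(A, B, max_value),
                         m=A.shape[0], n=A.shape[1], max_value=max_value)


def write_report_csv(path, reports, labels=None):
    """Write reports as CSV with the imperceptibility-table column order."""
    reports = list(reports)
    labels = labels or [f"pair{i + 1}" for i in range(len(reports))]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("image",) + REPORT_COLUMNS)
        for lab, rep in zip(labels, reports):
            w.writerow([lab] + rep.csv_row())
    return path
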