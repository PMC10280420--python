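"""Orthogonal Slantlet transform as an explicit N x N matrix.

The Slantlet transform is a wavelet-like orthogonal transform computed by a
parallel filter bank of short, piecewise-linear filters.  For an L-scale
basis on a length-N = 2**k signal the channels are

* an approximation channel: the block-constant filter of support 2**L,
* a "slant" channel: the centred block-linear filter of support 2**L
  (together these two represent any within-block affine trend exactly),
* for each scale i = 1 .. L-1 a pair of wavelet filters of support 2**(i+1)
  with *two* vanishing moments, one the shifted time-reverse of the other.

Each filter is supported on a single aligned block and shifted by its own
support, so the transform matrix is block structured and exactly orthogonal.
At L = 1 there are no wavelet pairs and the basis reduces entry-for-entry to
the orthonormal Haar transform.

The wavelet pair at scale i (block length 2m, m = 2**i) is pinned down by
its defining constraints: piecewise-linear over the two block halves, zero
0th and 1st moments, unit norm, and orthogonality to its own time-reverse.
Those constraints leave a single solution up to sign, obtained here in
closed form from the symmetric/antisymmetric split of the constraint space.

The 2-D transform of an image s is S = SLT_N . s . SLT_N^T and its inverse
is s = SLT_N^T . S . SLT_N; with approximation rows ordered first the four
quadrants of S are the LL / LH / HL / HH sub-bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import BasisMismatchError, ShapeMismatchError

__all__ = ["SlantletBasis", "SubbandSet", "build_slantlet_matrix",
           "slt_forward_2d", "slt_inverse_2d"]


@dataclass(frozen=True)
class SlantletBasis:
    """Orthogonal Slantlet matrix plus its row partition.

    ``partition`` maps a channel label to a ``(start, stop)`` row range.
    Labels are ``"approx"``, ``"slant"`` and ``"wavelet{i}"`` for the
    scale-i wavelet pairs (i = L-1 .. 1, coarse to fine).
    """

    matrix: np.ndarray
    scales: int
    partition: dict = field(compare=False)

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    @property
    def basis_id(self) -> str:
        return f"slt-N{self.size}-L{self.scales}"


@dataclass
class SubbandSet:
    """The four quadrants of a one-level 2-D Slantlet coefficient matrix."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray
    basis_id: str

    def assemble(self) -> np.ndarray:
        """Stitch the quadrants back into the full coefficient matrix."""
        top = np.hstack([self.LL, self.LH])
        bot = np.hstack([self.HL, self.HH])
        return np.vstack([top, bot])


def _wavelet_pair(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Scale filters (support 2m) with two vanishing moments, g and its
    time-reverse, mutually orthonormal.  Requires m >= 2."""
    n = np.arange(m, dtype=float)
    t = n - (m - 1) / 2.0
    # symmetric solution: centred ramp mirrored into the second half
    g_sym = np.concatenate([t, t[::-1]])
    g_sym /= np.linalg.norm(g_sym)
    # antisymmetric solution: first-moment condition fixes the offset
    alpha = (m * m - 1) / (6.0 * m)
    first = alpha + t
    g_asym = np.concatenate([first, -first[::-1]])
    g_asym /= np.linalg.norm(g_asym)
    g = (g_sym + g_asym) / np.sqrt(2.0)
    g_rev = (g_sym - g_asym) / np.sqrt(2.0)   # == g reversed in time
    return g, g_rev


@lru_cache(maxsize=32)
def _build(N: int, L: int) -> SlantletBasis:
    M = 2 ** L
    rows = []
    partition: dict[str, tuple[int, int]] = {}

    def add_channel(label, filt, step):
        start = len(rows)
        for off in range(0, N, step):
            r = np.zeros(N)
            r[off:off + filt.size] = filt
            rows.append(r)
        partition[label] = (start, len(rows))

    h = np.full(M, 1.0 / np.sqrt(M))                       # approximation
    t = np.arange(M, dtype=float) - (M - 1) / 2.0
    f = -t / np.linalg.norm(t)   # slant (descending ramp; Haar sign at M=2)
    add_channel("approx", h, M)
    add_channel("slant", f, M)
    for i in range(L - 1, 0, -1):                          # coarse -> fine
        m = 2 ** i
        g, g_rev = _wavelet_pair(m)
        start = len(rows)
        for off in range(0, N, 2 * m):
            for filt in (g, g_rev):
                r = np.zeros(N)
                r[off:off + 2 * m] = filt
                rows.append(r)
        partition[f"wavelet{i}"] = (start, len(rows))

    mat = np.array(rows)
    mat.setflags(write=False)
    return SlantletBasis(matrix=mat, scales=L, partition=partition)


def build_slantlet_matrix(N: int, L: int = 1) -> SlantletBasis:
    """Build (and cache) the orthogonal Slantlet basis SLT_N with L scales.

    Parameters
    ----------
    N : side length, a power of two.
    L : number of scales, 1 <= L <= log2(N).  L = 1 is the Haar-equivalent
        basis whose 2-D transform has the contiguous-quadrant sub-band
        layout used for embedding.
    """
    if N < 2 or (N & (N - 1)) != 0:
        raise ValueError(f"N must be a power of two >= 2, got {N}")
    k = N.bit_length() - 1
    if not 1 <= L <= k:
        raise ValueError(f"L must satisfy 1 <= L <= log2(N)={k}, got {L}")
    return _build(N, L)


def _as_array(gs) -> np.ndarray:
    # accept a GraySlice or a bare 2-D array
    return np.asarray(getattr(gs, "pixels", gs), dtype=float)


def slt_forward_2d(gs, basis: SlantletBasis) -> SubbandSet:
    """2-D Slantlet analysis: S = SLT_N . s . SLT_N^T, split into quadrants."""
    s = _as_array(gs)
    N = basis.size
    if s.shape != (N, N):
        raise ShapeMismatchError(f"slice shape {s.shape} != basis ({N}, {N})")
    S = basis.matrix @ s @ basis.matrix.T
    h = N // 2
    return SubbandSet(LL=S[:h, :h].copy(), LH=S[:h, h:].copy(),
                      HL=S[h:, :h].copy(), HH=S[h:, h:].copy(),
                      basis_id=basis.basis_id)


def slt_inverse_2d(sb: SubbandSet, basis: SlantletBasis) -> np.ndarray:
    """2-D Slantlet synthesis: s = SLT_N^T . S . SLT_N."""
    if sb.basis_id != basis.basis_id:
        raise BasisMismatchError(
            f"sub-bands built with {sb.basis_id}, basis is {basis.basis_id}")
    S = sb.assemble()
    if S.shape != (basis.size, basis.size):
        raise ShapeMismatchError(
            f"assembled coefficients {S.shape} != basis size {basis.size}")
    return basis.matrix.T @ S @ basis.matrix
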