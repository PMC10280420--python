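"""Householder reduction to upper-Hessenberg form, A = Q . H . Q^T.

The factor H has zeros below the first sub-diagonal; Q is the accumulated
product of Householder reflectors and its first column is e1.  The reflector
sign convention is pinned: for the working column tail x the reflector uses
v = x + sign(x1)||x|| e1 (sign(0) = +1), so the sub-diagonal entry that
survives is -sign(x1)||x||.  Columns whose below-sub-diagonal tail is
already negligible (<= 1e-12 ||A||_F) are skipped, so an input that is
already upper Hessenberg returns Q = I and H = A unchanged.

Adding a strictly-upper-triangular perturbation to H preserves the
Hessenberg structure, and because Q is orthogonal the perturbation's
Frobenius norm passes through reconstruction unchanged — the property the
embedding scheme relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeMismatchError

__all__ = ["HessenbergFactors", "hessenberg_decompose",
           "hessenberg_reconstruct", "similarity_transform"]

_SKIP_RTOL = 1e-12

#: reference 4x4 image block used by the decomposition demo and as a
#: deterministic test vector for the pinned reflector convention
EXAMPLE_4X4 = ((130.0, 245.0, 128.0, 134.0),
               (113.0, 226.0, 194.0, 231.0),
               (124.0, 212.0, 136.0, 245.0),
               (160.0, 189.0, 227.0, 145.0))


@dataclass
class HessenbergFactors:
    Q: np.ndarray
    H: np.ndarray

    @property
    def size(self) -> int:
        return self.H.shape[0]


def _check_square(A: np.ndarray, name: str = "A") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeMismatchError(f"{name} must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite entries")
    return A


def hessenberg_decompose(A) -> HessenbergFactors:
    """Factor a square matrix as A = Q . H . Q^T with H upper Hessenberg."""
    A = _check_square(A)
    n = A.shape[0]
    if n < 2:
        raise ShapeMismatchError("matrix must be at least 2 x 2")
    H = A.copy()
    Q = np.eye(n)
    skip_tol = _SKIP_RTOL * np.linalg.norm(A)
    for k in range(n - 2):
        x = H[k + 1:, k]
        if np.linalg.norm(x[1:]) <= skip_tol:
            continue
        v = x.copy()
        sign = 1.0 if x[0] >= 0 else -1.0
        v[0] += sign * np.linalg.norm(x)
        v /= np.linalg.norm(v)
        # apply P = I - 2 v v^T from both sides; accumulate into Q
        H[k + 1:, :] -= 2.0 * np.outer(v, v @ H[k + 1:, :])
        H[:, k + 1:] -= 2.0 * np.outer(H[:, k + 1:] @ v, v)
        Q[:, k + 1:] -= 2.0 * np.outer(Q[:, k + 1:] @ v, v)
    # zero out round-off below the first sub-diagonal
    H[np.tril_indices(n, -2)] = 0.0
    return HessenbergFactors(Q=Q, H=H)


def hessenberg_reconstruct(f: HessenbergFactors) -> np.ndarray:
    """Return Q . H . Q^T."""
    if f.Q.shape != f.H.shape:
        raise ShapeMismatchError(
            f"Q shape {f.Q.shape} != H shape {f.H.shape}")
    return f.Q @ f.H @ f.Q.T


def similarity_transform(B, Q, *, tol: float = 1e-8) -> np.ndarray:
    """Return Q^T . B . Q after checking that Q is orthogonal.

    Used at extraction time to recover the perturbed Hessenberg factor from
    the modified LL sub-band with the embedding-side Q.
    """
    B = _check_square(B, "B")
    Q = _check_square(Q, "Q")
    if B.shape != Q.shape:
        raise ShapeMismatchError(f"B shape {B.shape} != Q shape {Q.shape}")
    dev = np.abs(Q @ Q.T - np.eye(Q.shape[0])).max()
    if dev > tol:
        raise ValueError(f"Q is not orthogonal (max |QQ^T - I| = {dev:.3g})")
    return Q.T @ B @ Q
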