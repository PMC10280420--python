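"""Affine position scrambling of the watermark and its exact inverse.

A pixel at 1-based position (H, W) on the T x T grid is moved to

    (H', W') = S . (H, W) + t,   t = (a, b) if H < W - 1 else (1, b),

with both coordinates reduced modulo T back into 1..T.  The piecewise
translation means an integer matrix S with odd determinant is necessary but
not sufficient for the map to be a permutation, so ``validate_key``
enumerates all T^2 positions and rejects any key whose map collides.  The
inverse permutation is computed from the enumerated forward map, which makes
``unscramble(scramble(w)) == w`` exact by construction.

Keys serialize to JSON and are identified by a SHA-256 fingerprint of their
canonical form; extraction refuses a key whose fingerprint does not match
the one recorded at embedding time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import KeyRejectedError, ShapeMismatchError, WrongKeyError

__all__ = ["ScrambleKey", "ScrambledWatermark", "validate_key",
           "scramble", "unscramble", "default_key"]


@dataclass(frozen=True)
class ScrambleKey:
    """Validated affine scrambling key.

    Construct through :func:`validate_key`, which proves the induced
    position map is a bijection on the T x T grid.
    """

    S: tuple            # 2x2 integer matrix, rows as tuples
    a: int
    b: int
    T: int
    iterations: int = 1
    # forward permutation as flat index array, filled in by validate_key
    _perm: np.ndarray = field(default=None, compare=False, repr=False)

    def to_json(self) -> str:
        return json.dumps({"S": [list(r) for r in self.S], "a": self.a,
                           "b": self.b, "T": self.T,
                           "iterations": self.iterations},
                          sort_keys=True, separators=(",", ":"))

    @property
    def fingerprint(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    @property
    def is_validated(self) -> bool:
        return self._perm is not None


@dataclass
class ScrambledWatermark:
    """Permuted watermark values plus the fingerprint of the key used."""

    values: np.ndarray
    key_fingerprint: str


def _position_map(S: np.ndarray, a: int, b: int, T: int) -> np.ndarray:
    """Flat permutation candidate: entry r*T + c maps source (r, c) 0-based
    to destination flat index, following the 1-based algebra above."""
    Hs, Ws = np.meshgrid(np.arange(1, T + 1), np.arange(1, T + 1),
                         indexing="ij")
    Hp = S[0, 0] * Hs + S[0, 1] * Ws
    Wp = S[1, 0] * Hs + S[1, 1] * Ws
    branch_a = Hs < Ws - 1
    Hp = Hp + np.where(branch_a, a, 1)
    Wp = Wp + b
    Hp = (Hp - 1) % T
    Wp = (Wp - 1) % T
    return (Hp * T + Wp).ravel()


def validate_key(S, a: int, b: int, T: int, iterations: int = 1) -> ScrambleKey:
    """Enumerate the induced position map and return the key iff bijective.

    Raises
    ------
    KeyRejectedError
        naming the first colliding pair of source positions.
    """
    S = np.asarray(S, dtype=int)
    if S.shape != (2, 2):
        raise ValueError("S must be a 2x2 integer matrix")
    if T < 2:
        raise ValueError("T must be >= 2")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    dest = _position_map(S, int(a), int(b), T)
    counts = np.bincount(dest, minlength=T * T)
    if counts.max() > 1:
        hit = int(np.flatnonzero(counts > 1)[0])
        srcs = np.flatnonzero(dest == hit)[:2]
        pos = [(int(s) // T + 1, int(s) % T + 1) for s in srcs]
        raise KeyRejectedError(
            f"position map is not a bijection: sources {pos[0]} and {pos[1]} "
            f"(1-based) both map to ({hit // T + 1}, {hit % T + 1})")
    key = ScrambleKey(S=tuple(tuple(int(v) for v in row) for row in S),
                      a=int(a), b=int(b), T=T, iterations=int(iterations))
    object.__setattr__(key, "_perm", dest)
    return key


def default_key(T: int = 64, iterations: int = 5) -> ScrambleKey:
    """The package default: S = [[1, 1], [1, 2]] (det 1), a = 1, b = 2."""
    return validate_key([[1, 1], [1, 2]], 1, 2, T, iterations)


def _check_key(key: ScrambleKey):
    if not isinstance(key, ScrambleKey) or not key.is_validated:
        raise KeyRejectedError("key has not been validated; use validate_key")


def scramble(watermark, key: ScrambleKey) -> ScrambledWatermark:
    """Permute watermark pixel positions ``key.iterations`` times."""
    _check_key(key)
    w = np.asarray(watermark, dtype=float)
    if w.shape != (key.T, key.T):
        raise ShapeMismatchError(
            f"watermark shape {w.shape} != ({key.T}, {key.T})")
    flat = w.ravel().copy()
    out = np.empty_like(flat)
    for _ in range(key.iterations):
        out[key._perm] = flat
        flat, out = out, flat
    return ScrambledWatermark(values=flat.reshape(key.T, key.T),
                              key_fingerprint=key.fingerprint)


def unscramble(sw: ScrambledWatermark, key: ScrambleKey) -> np.ndarray:
    """Invert :func:`scramble` exactly via the enumerated forward map."""
    _check_key(key)
    if sw.key_fingerprint != key.fingerprint:
        raise WrongKeyError(
            "key fingerprint does not match the one used for scrambling")
    flat = np.asarray(sw.values, dtype=float).ravel().copy()
    for _ in range(key.iterations):
        flat = flat[key._perm]
    return flat.reshape(key.T, key.T)
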