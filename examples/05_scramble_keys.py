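"""Affine scramble keys: validation, rejection, and exact inversion.

A key is accepted only after exhaustive enumeration proves its position map
permutes the whole T x T grid; the piecewise translation of the map means
even an odd-determinant matrix can collide, so validation is not optional.
"""

import numpy as np

import niftimark as nm
from niftimark.errors import KeyRejectedError

key = nm.default_key(T=64, iterations=5)
print(f"default key accepted, fingerprint {key.fingerprint[:16]}...")

logo = nm.make_watermark(64)
scrambled = nm.scramble(logo, key)
print(f"scrambled: value multiset preserved = "
      f"{sorted(scrambled.values.ravel()) == sorted(logo.ravel())}")
back = nm.unscramble(scrambled, key)
print(f"unscramble(scramble(w)) == w exactly: "
      f"{np.array_equal(back, logo)}")

try:
    nm.validate_key([[2, 0], [0, 2]], a=0, b=0, T=8)
except KeyRejectedError as exc:
    print(f"even-determinant key rejected: {exc}")

try:
    nm.validate_key([[1, 1], [1, 2]], a=0, b=0, T=8)
except KeyRejectedError as exc:
    print(f"colliding piecewise translation rejected: {exc}")
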