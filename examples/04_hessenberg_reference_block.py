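"""Decompose the built-in 4x4 reference image block, A = Q H Q^T.

Prints the orthogonal factor Q and the upper-Hessenberg factor H (zeros
below the first sub-diagonal) under the pinned Householder sign convention,
plus the reconstruction residual.  The sub-diagonal entry H[2][1] equals
-||(113, 124, 160)|| = -231.8297 by construction.
"""

import numpy as np

import niftimark as nm

A = np.array(nm.EXAMPLE_4X4)
fac = nm.hessenberg_decompose(A)

np.set_printoptions(precision=4, suppress=True, floatmode="fixed")
print("A =\n", A)
print("Q =\n", fac.Q)
print("H =\n", fac.H)
resid = np.linalg.norm(nm.hessenberg_reconstruct(fac) - A)
print(f"||Q H Q^T - A||_F = {resid:.3e}   (exact up to float round-off)")
print(f"trace(H) = {fac.H.trace():.4f} = trace(A) = {A.trace():.1f} "
      "(similarity invariant)")
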