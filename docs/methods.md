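# Methods

## Model

niftimark implements transform-domain, non-blind watermarking of a single
slice of a NIfTI-1 volume. The carrier slice is converted to the [0, 255]
gray scale by an invertible linear min–max rescale (endpoints stored, so
slice extraction/replacement is an exact inverse pair). The embedding chain
is

    X  →  SLT analysis  →  LL  →  Q·H·Qᵀ  →  H′ = H + μ·𝕎  →
    LL′ = Q·H′·Qᵀ  →  inverse SLT (original LH/HL/HH)  →  X′

with 𝕎 the affine-scrambled watermark placed in a strictly
upper-triangular T×T block of H. Extraction reverses the chain using the
original slice: `H* = Qᵀ·LL*·Q`, `𝕎 = (H* − H)/μ`, inverse permutation.

Assumptions worth stating explicitly:

* **The scheme is non-blind and precision-sensitive.** Extraction reuses
  the orthogonal factor Q of the *original* LL sub-band. For smooth medical
  slices LL is numerically near low rank, and the trailing Householder
  reflectors — hence the trailing columns of Q — are not stable under
  perturbations of the original. The original must therefore be available
  at the precision used at embedding time. Consequences: watermarked output
  defaults to float32 (and float64 is available for bit-exact round trips),
  and the phantom generator emits float32-representable voxels so the
  original survives the default file round trip bit-exactly. With float64
  files end-to-end recovery is exact to 1e-9; with float32 files the
  watermarked side is quantized and the measured NC deviation is ~2e-8 at
  μ = 0.01.
* **Re-decomposition does not invert the embedding.** A fresh Hessenberg
  factorization of LL′ does not return H + μ𝕎 (the reflectors change once
  the perturbation is present), so the default extraction mode is the
  similarity transform with the original Q; the literal re-decomposition
  route is kept as `extraction_mode="redecompose"` for experiments, and a
  test documents that it is strictly worse.
* Watermark values are embedded on their raw [0, 255] scale (not
  binarized), and watermarked pixels are not clamped: clamping would break
  the closed-form MSE/PSNR identities. Attacks, by contrast, do clip to
  [0, 255], because they model degradation of a display-scale image.

## Slantlet basis

The L-scale basis on N = 2^k points is a block-structured orthogonal
matrix: per 2^L-block a constant (approximation) row and a centred-linear
("slant") row, plus, for each scale i = 1..L−1, a wavelet pair of support
2^(i+1) with two vanishing moments, one filter the shifted time-reverse of
the other. The pair is obtained in closed form from the
symmetric/antisymmetric decomposition of the 2-dimensional space of
blockwise piecewise-linear vectors with vanishing 0th and 1st moments;
within that space the orthogonality-to-time-reverse condition fixes the
filters uniquely up to sign. Orthogonality of the whole matrix follows
because every coarser filter restricted to a finer aligned block is affine
there and is annihilated by the two vanishing moments.

At L = 1 the basis equals the orthonormal Haar matrix entry-for-entry
(slant row sign pinned to the descending ramp, `[1, −1]/√2`). L = 1 is the
default — the four-quadrant LL/LH/HL/HH layout used for embedding is a
one-level structure — and L ≥ 2 bases sit behind the `scales` knob of
`EmbedConfig`. Bases are cached per (N, L).

## Hessenberg decomposition

Householder reduction with the reflector sign pinned to
`v = x + sign(x₁)·‖x‖·e₁`, `sign(0) = +1`, so the surviving sub-diagonal
entry is `−sign(x₁)·‖x‖`. This convention makes the built-in 4×4 reference
block a deterministic test vector (`H[2][1] = −‖(113,124,160)‖ =
−231.8297`). Columns whose below-sub-diagonal tail is already ≤ 1e-12·‖A‖_F
are skipped, so an upper-Hessenberg input returns Q = I, H = A exactly.
LAPACK (via scipy) serves as an independent cross-check in the tests — the
two factorizations may differ in per-column reflector signs, so the
comparison is on magnitudes and reconstructions.

## Scrambling

The position map is the 1-based piecewise affine map

    (H′,W′) = S·(H,W) + t,   t = (a,b) if H < W−1 else (1,b),

with both coordinates reduced mod T into 1..T. The printed form of the map
has no modulus and its two branches can collide even for unimodular S, so
`validate_key` enumerates all T² positions and rejects any non-bijective
key, naming the first collision. The inverse is taken from the enumerated
forward map, never from the inverse formula, so unscrambling is exact by
construction. Default key: S = [[1,1],[1,2]] (det 1), a = 1, b = 2, five
iterations — with a = 1 both branches apply the same translation, making
the map a pure unimodular affine bijection at any T. Keys are identified
by the SHA-256 of their canonical JSON; extraction refuses a mismatched
fingerprint rather than returning a silently garbled watermark.

## Parameters

| parameter | default | meaning |
|---|---|---|
| μ (embedding strength) | 0.01 | scale of the additive perturbation of H; trades imperceptibility (small μ) against robustness (large μ). `calibrate_mu` solves μ for a PSNR target, e.g. 60.5 dB → μ ≈ 0.0169 for the built-in logo. |
| T (watermark side) | 64 | must satisfy T ≤ N/4 so the block fits strictly above the diagonal of the (N/2)×(N/2) factor |
| placement | rows 1..T, cols N/2−T+1..N/2 | top-right corner of H; any strictly-upper block is accepted |
| L (Slantlet scales) | 1 | one-level quadrant structure |
| scramble iterations | 5 | repeated application of the position permutation |

All sidecar coordinates are 0-based (`coordinate_convention` field in the
embed record).

## Metrics

MSE, PSNR, SNR, NC, the universal quality index Q and SSIM. NC uses the
asymmetric normalization `Σ(w·w*)/Σw²` — exactly 1 for a perfect copy,
*linear* in the extracted image, and therefore able to exceed 1; it is a
recovery score, not a bounded correlation. Q is evaluated globally (one
window, population moments). SSIM is the standard mean-local form (11×11
Gaussian window, σ = 1.5, stabilizers (0.01·255)², (0.03·255)²), delegated
to scikit-image and cross-checked in the tests against an independent
sliding-window implementation; images smaller than the window fall back to
a single global window with a warning. Zero-error PSNR/SNR report an
explicit `inf` sentinel.

## Attacks and the robustness bench

Noise variances and densities are interpreted on the unit-normalized scale
and mapped back to [0, 255] (the convention of the toolbox whose settings
the catalog mirrors). Interpretation choices where the settings are
ambiguous: motion blur "0.2" becomes a horizontal kernel of length
max(2, round(0.2·15)) = 3; sharpening "0.2" is an unsharp mask with a 3×3
Laplacian and amount 0.2; the Gaussian low-pass uses a 3×3 kernel with
σ = 0.5. Stochastic attacks draw from PCG64 seeded per spec; zero-severity
attacks are exact identities. A unit-scale Poisson attack is available but
excluded from the default ten.

The bench embeds once, then attacks/extracts/scores per spec. The
extracted watermark is clipped to [0, 255] before scoring, since it is
reported as an 8-bit-range image. This matters for NC: unclipped, the
asymmetric NC picks up a bias linear in attack severity (e.g. the
salt & pepper mean shift maps through the linear pipeline) and can rise
above 1 with increasing density; clipped, mean NC degrades monotonically
with severity, as expected of a recovery score. Attack-free rows are
unaffected (< 1e-6 gray levels).

## Phantom generator

Phantom slices are a seeded elliptical body with internal ellipses plus a
smooth low-amplitude texture, clipped to [0, 255]; volumes stack
perturbed copies of a base slice (through-plane correlation > 0.9) with a
1 mm isotropic header. All randomness flows through PCG64 with explicit
seeds, so fixtures are bit-identical across platforms. What the phantoms
do **not** emulate: anatomy, scanner noise statistics, Hounsfield
calibration, or intensity ranges beyond [0, 255]. Passing tests therefore
demonstrate the algebraic and statistical behaviour of the pipeline, not
clinical imperceptibility on real scans; on real data the closed forms
still hold exactly (they are properties of the transforms, not the image),
but robustness numbers will differ with image content and μ.

## Problem sizes in the test suite

The default suite exercises the full 512×512 slice / 64×64 watermark
configuration for fidelity, imperceptibility and the ten-attack bench, and
smaller powers of two (32–256) where the property under test is
size-independent. The salt & pepper monotonicity check averages five seeds
per density over {0.001, 0.003, 0.01}.

## Known limitations

* Non-blind only; no ROI/RONI segmentation; single-slice embedding.
* No geometric attacks (rotation, cropping, scaling) in the catalog.
* The scrambling map is a fixed permutation per key — it hides layout but
  is not a cryptographic primitive; the EPR sidecar is plaintext.
* int16 output quantizes the embedding perturbation and breaks the
  closed-form identities; it is opt-in (`allow_clip` guards range
  overflow).
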