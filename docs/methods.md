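# Methods

## Model and procedure

The reconstruction target is a complex-valued N×N MR image `I_t` observed
only through undersampled k-space measurements `y = U ⊙ F I_t (+ ε)`,
where `F` is the centered, orthonormal 2-D DFT, `U` a binary sampling
mask, and `ε` optional complex Gaussian measurement noise. No training
data is used. An untrained encoder-decoder CNN with skip connections
`f(θ|·)` is optimized per image by Adam on the k-space data-fidelity loss
`‖y − U ⊙ F f(θ|I_r)‖₂²`, with the network input held fixed: either a
reference image `I_r` of similar anatomy (reference-driven mode) or a
seeded white-noise tensor (classic deep-image-prior mode). After the
fixed iteration budget, the data-correction step overwrites the network
output's k-space with the measurements wherever they exist; the final
image is the inverse DFT of the corrected k-space. Consequently the
reconstruction is exactly data-consistent at sampled locations (to the
roundoff of one FFT round trip), the correction is idempotent, and at
100% sampling the method returns the target exactly regardless of the
network state.

Complex images pass through the real-valued network as two channels
(real, imaginary). The loss gradient with respect to the complex output
is computed analytically — `2 Fᴴ(U ⊙ (F x − y))`, using that `F` is
unitary so its adjoint is its inverse — and then backpropagated through
the network layers.

## Network

Per depth *i* of *L*: a down block (stride-2 conv `kd[i]` → batch norm →
leaky-ReLU → conv → BN → leaky-ReLU, `nd[i]` filters), a skip block
(conv `ks[i]` → BN → leaky-ReLU, `ns[i]` filters) branching off before
the downsampling, and an up block (BN over the concatenated skip and
bilinearly ×2-upsampled deeper features → conv `ku[i]` → BN → leaky-ReLU
→ 1×1 conv → BN → leaky-ReLU, `nu[i]` filters), with a final 1×1 conv to
the output channels. Input sizes must be divisible by `2^L`. The exact
composition inside each block follows the standard deep-image-prior
architecture that this design adopts; downsampling by strided
convolution and upsampling by bilinear interpolation are fixed.

Choices not pinned down elsewhere, with defaults:

| parameter | default | rationale |
|---|---|---|
| leaky-ReLU slope | 0.1 | standard deep-image-prior choice; configurable |
| padding | reflection | avoids dark border artifacts of zero padding |
| weight init | He-normal, seeded | matches leaky-ReLU gain; seed on the spec |
| optimizer | Adam, lr 0.01 | the learning rate of the published configs; plain SGD diverges at this loss scale |
| batch norm | per-channel over space, eps 1e-5 | batch of one image, so BN acts as instance norm |
| loss | complex ℓ₂ on sampled k-space entries only | stacked real/imag ℓ₂ is mathematically identical |
| reference scaling | divided by its max magnitude | stabilizes BN statistics; the k-space loss anchors the output scale, so no inverse scaling is applied |
| input mode | complex two-channel | a magnitude-only single-channel mode exists for real phantoms |
| stopping | fixed iteration count, no early stopping | the published schedule; metric traces sampled every `eval_every` = 100 iterations |

The layers are implemented directly in numpy (im2col convolutions,
explicit backward passes, Adam) and are validated against
finite-difference gradients in the test suite.

## Masks

The three families target a requested sampling rate and achieve it
within ±0.02 for N ≥ 64:

* **Cartesian** — full rows; a centered fully sampled band holds 32% of
  the sampled lines, the rest are drawn without replacement with density
  `1/(1 + (d/(N/8))²)` in the distance *d* from the center row.
* **Radial** — equiangular spokes through DC, rasterized at 0.5-pixel
  steps with a seeded angular offset; the spoke count is found by
  bisection on the achieved rate. Rates unreachable by any spoke count
  raise an error naming the achievable bound.
* **Variable-density** — pointwise, density `(1 + r/r₀)^(−decay)` with
  `r₀ = N/16` and `decay = 2` by default, plus an always-sampled central
  disk of radius N/32. Exactly `round(rate·N²)` entries are selected by
  weighted sampling without replacement (exponential-key top-k), so the
  achieved rate is exact by construction rather than Bernoulli-
  approximate — a deliberate choice so the rate contract holds for every
  seed, not just in expectation.

No published generation algorithm exists for these patterns (only example
images); the profiles above are package choices, parameterized so they
can be tuned.

## Metrics

Relative error `‖x̂−x‖₂/‖x‖₂`, PSNR `10·log₁₀(MAXₓ²/MSE)` (infinite for
identical images), and SSIM — all on magnitude images, the universal
convention in this literature. SSIM has two modes: **global** evaluates
the SSIM formula once on whole-image statistics with absolute constants
c₁ = 0.01, c₂ = 0.03 (a literal, dynamic-range-free form retained for
reproducibility of that definition); **windowed** (default) is the
standard Wang et al. form — 11×11 Gaussian windows, σ = 1.5, constants
(0.01·D)² and (0.03·D)². D is taken as the joint dynamic range of the
two images so the metric is symmetric in its arguments. The windowed
implementation is validated against both a brute-force sliding-window
oracle and scikit-image's implementation.

## Synthetic data

`make_phantom_pair` draws a skull-like ring plus `n_structures = 8`
random ellipses (rendered at 4× supersampling for anti-aliased edges) as
the reference; the target repeats the same scene with centers and axes
jittered by up to 1.5 px, intensities by up to 10%, and one extra small
ellipse (a lesion analogue) present only in the target. Pairs must land
in a windowed-SSIM band of [0.55, 0.98] — similar but not identical —
else they are regenerated (up to 10 attempts). The defaults are
calibrated for the 64×64 study size; at smaller sizes the same pixel
jitter is proportionally larger, so tests on 32×32 images use
jitter 0.75 px / 5%. An optional smooth low-order phase map makes images
genuinely complex; a resized Shepp–Logan phantom is provided as a
regression fixture.

Measurement noise is added in k-space: circularly symmetric complex
Gaussian with std `sigma` **relative to a named k-space statistic** (std
or max of the noiseless k-space). An absolute noise std is meaningless
against phantoms of arbitrary intensity scale, so the scale reference is
explicit rather than hard-coded.

What the phantoms do *not* emulate: coil sensitivities, T1/T2 contrast,
field inhomogeneity, motion, or the texture statistics of real brain
tissue. Passing benchmarks here show the pipeline ranks methods correctly
and honors its contracts on controlled inputs; they do not certify
clinical image quality.

## Study conditions for the benchmark

The packaged comparison (tests and `scripts/acceptance.py`) runs the
64×64 phantom pair with a depth-3 network (nd = nu = [16, 32, 64],
ns = [4, 4, 4], kernels 3/3/1), 500 iterations at lr 0.01, and 5 seeds
per method — a desk-scale rendition of the published design (512×512 or
256×256 scans, depth 5–6, 5000 iterations, 30 repetitions), chosen so a
full comparison completes in minutes on one CPU core while preserving
the qualitative structure: reference-driven > classic DIP > zero-filling
in mean PSNR (reversed in relative error), a decreasing relative-error
trace between iterations 100 and 500, and the same PSNR ordering under
k-space noise at sigma = 0.05 of the k-space std with a radial 30% mask.
The full-scale configurations remain available as packaged configs and
flags.

## Numerical notes and limitations

* FFTs are orthonormal and centered (DC at `N//2`); all operators are
  exactly unitary/adjoint and tested against an O(N⁴) naive DFT oracle.
* Measurements are stored as (mask, dense grid) pairs; the degenerate
  empty mask is representable but rejected by reconstruction entry
  points.
* The optimization is non-convex and Adam is non-monotone per step; only
  start-vs-end loss decrease and seed-averaged orderings are guaranteed
  by tests, not per-iteration monotonicity.
* Determinism: every random element (phantom, mask, noise, weight init,
  noise input) is governed by an explicit integer seed; reruns are
  bit-identical.
* Single-coil, 2-D, Cartesian-grid sampling only; true non-Cartesian
  trajectories (NUFFT/gridding), parallel imaging, and GPU execution are
  out of scope.
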