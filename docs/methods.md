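# Methods

## Scope and model

`destreak` studies streak-artifact removal in sparse-view fan-beam CT under
the additive corruption model `f = x + n`: a sparse-view FBP reconstruction
`f` equals the full-view reconstruction `x` (the gold standard) plus a
structured streak field `n`.  A convolutional network μ(f; Θ) is trained to
predict `n`; correction is the subtraction `x̂ = f − μ(f)`.  Residual
learning is preferred over direct image prediction because `f` is already a
good approximation of `x`, so a direct map would have to reproduce an
identity plus a small perturbation, whereas the residual target carries all
of its energy in the quantity of interest.

Everything is 2D: slices, not volumes.  Projections are noise-free — view
sparsity is the only corruption modeled — so measured improvements isolate
the streak-removal problem from dose/noise questions.

## Phantoms (the synthetic data generator)

Objects are ordered lists of ellipses whose attenuation values add where
they overlap.  Additivity gives two exact primitives:

* **Rendering** samples pixel centers (no anti-aliasing): a pixel equals the
  sum of attenuation values of the ellipses strictly containing its center.
  This makes renders bit-for-bit reproducible and exactly linear in the
  attenuation values.
* **Line integrals** are closed-form: each ellipse contributes its
  attenuation times the chord length from the line/ellipse quadratic.  The
  analytic sinogram is therefore exact up to float rounding and serves as
  the oracle for the numerical projector and FBP.

Random phantoms emulate the role of a large clinical training set: a
background disk of attenuation 1.0 (radius 0.95 × FOV/2) plus 4–12 ellipses
with centers uniform in a disk of 0.8 × FOV, semi-axes between 0.05 and
0.35 × FOV/2 (capped so every ellipse stays inside the FOV), rotations
uniform in [0°, 180°), and attenuation increments uniform in [0.05, 0.5].
All increments are positive, so renders are non-negative by construction.
The sharp, randomly oriented edges are what generate streaks under
sparse-view FBP.  What these phantoms do **not** emulate: anatomical
texture, soft-tissue gradients, projection noise, or scanner
non-idealities — a network trained here demonstrates the method, it is not a
clinically trained model.  The fixed 10-ellipse head phantom is used for
accuracy benchmarks.

The default field of view is 170 mm, chosen to sit just inside the fan
coverage of the default geometry (175.7 mm, see below).

## Geometry and projector

Flat-detector (equispaced) fan-beam geometry with the scanner defaults:
source-to-detector 988.00 mm, source-to-isocenter 560.00 mm, detector width
313.89 mm, full 360° rotation, 720 views.  Sparse protocols subsample views
by exact strides: every 6th view → 120 views (3° increment), every 12th →
60 views (6° increment).  Angle 0 places the source on the +y axis; angles
increase counter-clockwise.  Conventions (origin at image center, x right,
y up, mm units, image row 0 at top) are fixed package-wide and asserted in
tests.

The detector bin count is not part of the emulated protocol; by default the
dataset builder chooses it so the bin pitch projected to the isocenter is
half a pixel (e.g. 268 bins for 128² over 170 mm), which keeps detector
sampling from limiting reconstruction quality.  For arbitrary images a
ray-driven numerical projector (¼-pixel sampling step, bilinear
interpolation) complements the analytic one; it is linear in the image and
agrees with the analytic sinogram to well under 2% relative ℓ2 at 256².

## FBP

Classical equispaced fan-beam FBP: detector coordinates rescaled to a
virtual detector through the isocenter, cosine pre-weighting
R/√(R² + u²), convolution with the band-limited Ram-Lak ramp (spatial
closed form: 1/(4Δ²) at lag 0, zero at even lags, −1/(πkΔ)² at odd lags),
and backprojection with the R²/U² distance weight and Δβ/2 angular weight
(the ½ because a full rotation measures every ray twice).  A Hann-windowed
variant of the ramp is available; Ram-Lak is the default since the
"well-known FBP" baseline is conventionally unapodized.  Short-scan (Parker)
weighting is not implemented — full rotations only.

Reconstructions keep negative values; clipping to the display range happens
only at 16-bit export.  This keeps the residual `f − x` unbiased.

Numerical behavior worth knowing: at practical sampling (720 views, ~0.2 mm
effective bins) the head-phantom reconstruction error is ≈10% relative ℓ2,
dominated by edge ringing — comparable to (and in our measurements slightly
better than) a parallel-beam reference implementation on the same phantom.
Shift equivariance holds only up to this discretization error: rolling the
reconstruction of a shifted phantom explains >85% of the difference and the
residual decays roughly as the inverse square root of the sampling density,
but it does not vanish.  The truncation flag on reconstructions is raised
when the sinogram carries signal in its outermost detector bins (the
standard sign that the object extends beyond the fan).

## Artifact network

Architecture (fully convolutional, any square input ≥ 32 px):

1. 3×3 conv (1 → C) + ReLU
2. 3×3 conv (C → C) + BN + ReLU
3. B inception blocks: parallel conv branches with kernels {1, 3, 5, 7},
   each C → C/4 with BN + ReLU, concatenated back to C channels
4. 3×3 conv (C → 1), no activation

Defaults C = 64, B = 8 (727,937 parameters); the desk-scale profile
`NetworkConfig.small()` uses C = 32, B = 2 (53,121 parameters).  No pooling
and no strides anywhere: the output must stay same-resolution for the final
subtraction.  `multiscale=False` replaces each inception block with one
3×3 C → C conv + BN + ReLU — the one-scale baseline of equal depth and
trunk width.

The branch composition within an inception block (equal channel shares,
kernels 1/3/5/7) is a declared design choice: multi-scale kernels are the
point of the block, and equal shares preserve the trunk width without extra
projection layers.

Initialization is seeded He fan-in scaling with one deliberate exception:
the head conv starts at zero, so the untrained network predicts a zero
artifact image and training begins exactly at the identity correction
(x̂ = f).  With a random head the initial prediction is large noise and a
short training budget is spent undoing it; with the zero head every
gradient step can only improve on raw FBP.  BN starts as identity (γ = 1,
β = 0, running stats 0/1).

Inputs are normalized by the stored-intensity scale 4095 (12-bit storage
convention) on the way in; predictions are rescaled on the way out, so
`correct_image` operates in stored units and metrics use peak 4095.

### NumPy implementation notes

The layers (convolution, batch norm, ReLU) carry hand-written backward
passes.  Convolutions have two numerically identical execution paths — a
direct tap loop (one GEMM per kernel tap) and a spectral path (rFFT, batched
complex matmul, inverse rFFT) — chosen by a fixed work heuristic (spectral
for kernels ≥ 5).  Inside an inception block the spectral branches share a
single input FFT, their input-gradient spectra are summed so one inverse
transform serves all branches, and weight gradients are evaluated only at
the k² needed lags with small DFT matrices instead of a full inverse
transform.  Path parity and gradients are verified in the test suite
(finite differences in float64, tolerance 1e-4 relative with a 1e-5 absolute
floor — the floor matters because conv biases feeding BN have exactly zero
gradient).

## Training

Pairs (f, x) are built per phantom from one analytic 720-view sinogram:
x = FBP of all views, f = FBP of the subsampled views; both mapped to
stored units with attenuation 2.5 ↔ 4095 (random phantoms peak near 2, so
typical tissue sits in the upper half of the 12-bit range without
clipping).  Dataset generation is deterministic given a seed; per-phantom
seeds come from a `SeedSequence` and are recorded in the manifest, so a
dataset can be regenerated bit-for-bit from its provenance.

Optimization: Adam (β = 0.9/0.999, ε = 1e-8), learning rate 1e-3, batch
size 8, whole-image training, seeded shuffling, optional random-patch mode
and early stopping on a validation plateau.  The loss reported by the loop
is computed with a float64 subtraction of the float32 tensors, which makes
it agree bit-for-bit with the standalone `residual_loss` on the same batch.
Divergence (non-finite loss) aborts with a diagnostic rather than returning
garbage.

Problem sizes for the bundled experiments are desk-scale by design: the
core experiment trains the small profile on 200 random 128² phantoms at 60
views for 8 epochs (about six minutes on one CPU) and evaluates on 20
held-out phantoms.  In a representative run this lifts mean PSNR from
31.7 dB to 42.4 dB and SSIM from 0.81 to 0.98 against the 720-view gold
standard.  The acceptance threshold (≥ 2 dB mean PSNR gain, SSIM strictly
increasing) is deliberately far below the observed gain; it asserts the
direction and robustness of the effect, not a fragile point estimate.  The
multi-scale/one-scale comparison is run at an even smaller scale and only
*reported*: at desk scale the two variants are within a dB of each other,
and which one leads is budget- and data-dependent.

## Metrics

PSNR = 10·log10(peak²/MSE) with peak fixed at 4095 (12-bit convention) —
a fixed peak keeps values comparable across images; identical images report
+∞.  SSIM uses the canonical parameters: 11×11 Gaussian window (σ = 1.5),
C1 = (0.01·peak)², C2 = (0.03·peak)², sample-mean over windows fully inside
the image; negative local values are retained (the nominal [0, 1] range
describes typical outputs, not a clamp).  The implementation matches
scikit-image's SSIM to better than 1e-6, which the tests assert against that
independent reference.

## Numerical fine print

* `x = f − μ(f)` is exact algebra, but `f − (f − x) == x` is only bit-exact
  in floating point where the Sterbenz condition holds; on integer-valued
  stored counts (the 12-bit storage format) it is always bit-exact, and on
  raw float reconstructions it holds to 1 ulp.
* FBP linearity and zero-input behavior are exact (the pipeline is linear);
  reconstruction *accuracy* is sampling-limited as described above.
* Seeded runs are reproducible on a given platform; across BLAS/FFT builds,
  float32 results may differ at the last bit.

## Known limitations

* Phantoms are piecewise-constant ellipse composites; no claim is made that
  a network trained on them transfers to clinical texture.
* 2D fan-beam only: no helical/cone-beam geometry, no rebinning of real
  scanner data.
* No projection noise, scatter, beam hardening, or detector blur.
* No iterative reconstruction baselines; FBP is the only reconstruction
  engine.
* The full-size network (64 channels, 8 blocks) is provided and tested for
  correctness, but the bundled experiments train the small profile; CPU
  training of the full model at clinical scale is out of scope.
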