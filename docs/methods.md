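# Methods

## Problem setting

MRI raw data are acquired in k-space, the 2-D spatial-frequency domain.
Thermal acquisition noise is additive i.i.d. complex Gaussian there,
`y = x + n` with per-channel standard deviation σ, and because the
k-space ↔ image transform used throughout this package is unitary
(orthonormal FFT, zero frequency centred), the noise is *also* i.i.d.
complex Gaussian with the same σ in the complex image.  Denoising is
therefore done on the two-channel (real, imaginary) image — converting
to magnitude first would turn the noise Rician and break both methods'
Gaussian assumptions.  No clean targets exist for in-vivo MRI, so both
learned denoisers are self-supervised: they train on noisy data alone.

## MC-SURE U-Net

Stein's unbiased risk estimator replaces the supervised batch MSE
`(1/M) Σ_j ‖h(y_j;θ) − x_j‖²` with

    (1/M) Σ_j [ ‖y_j − h(y_j)‖² − Kσ² + 2σ² div h(y_j) ],

which has the same expectation without referencing `x`.  `K` counts real
scalars per sample — 2 per complex pixel — because the noise model is
per-channel; the unbiasedness test fails under a per-complex-pixel count.
The divergence is intractable for a deep network and is replaced by the
Monte-Carlo probe `div h(y) ≈ (1/ε) ñᵀ[h(y + εñ) − h(y)]` with one fresh
standard-normal field ñ per sample per step.  The probe is *divided* by
ε: multiplying by ε would make the term vanish as ε → 0, and only the
divided form matches the brute-force `2σ²·tr(A)` oracle for an explicit
linear filter (asserted in the tests).  ε defaults to 1e-3 × the batch
peak magnitude; for a linear denoiser the loss is empirically flat in ε
across [1e-4, 1e-2] × data scale.

The denoiser is a two-channel U-Net: per level two 3×3 convolutions with
LeakyReLU (slope 0.1), 2×2 max-pool down with feature doubling, nearest-
neighbour upsampling + convolution up, skip connections by channel
concatenation, and a linear 1×1 output layer.  The full-scale protocol is
depth 5 / 48 base features / batches of 10 / 300 epochs / Adam 3e-4;
inputs not divisible by 2^depth are reflect-padded and cropped back.

## Blindspot network with posterior-mean inference

A blindspot network predicts each pixel from context that excludes the
pixel itself, so the network cannot win by copying its input.  The
construction: a single stack of "causal" convolutions (each 3×3 layer
padded 2 rows on top, none below, so the receptive field stays in rows
≤ r) is applied, with shared weights, to the four 90° rotations of the
input; a one-pixel downward shift then makes the half-plane strict; the
counter-rotated branches are concatenated and fused by two linear 1×1
convolutions into a per-pixel Gaussian prior: two mean channels μ and two
variance channels through a softplus (+1e-8 floor).  The union of four
strict half-planes covers everything except the centre pixel; the
conformance criterion is the measured Jacobian (finite-difference
sensitivity of the output at p to the input at p is exactly 0), not any
particular reference implementation.  Branch convolutions carry the
LeakyReLU nonlinearity; the fusion/output head is linear.

Training minimises the negative log-likelihood of the observed pixel
under the predictive marginal `y ~ N(μ, var + σ²)` (σ known, per the
estimator below).  At test time the centre pixel re-enters through the
conjugate-Gaussian posterior mean

    E[x | y, context] = (μσ² + y·var) / (var + σ²),

which returns `y` exactly at σ = 0 and `μ` as var → 0, and always lies
between μ and y channel-wise.  The learning rate is halved when the
validation loss (last sixth of the training slices if no explicit split
is given) has not improved for `lr_patience` epochs (default 10).
A diagonal per-channel variance is used rather than a full 2×2 complex
covariance: σ is scalar per channel throughout the noise model, and the
diagonal form keeps the posterior closed-form elementary.

## Input scaling

Both networks are sensitive to the absolute input scale (the SURE loss
catastrophically so, since σ² and the data enter on fixed scales).  Each
protocol therefore rescales inputs: ×500 for the knee protocol, ×1/25000
for the brain protocol, ×1/2000 for the desk phantom protocol (mapping
its peak intensity 2000 to 1).  Models record the scale they were
trained under and rescale/restore at inference; a heuristic warns when an
input's median magnitude is >100× off the training scale.

## Background σ estimation

MRI slices have large zero-signal regions where the magnitude of pure
complex Gaussian noise is Rayleigh(σ).  The estimator seeds itself with
the lowest `background_fraction` (default 0.1) of pixels by magnitude but
does **not** report their raw pooled standard deviation: selecting the
lower tail of a Rayleigh truncates it, biasing a plain standard deviation
to ≈0.23σ at fraction 0.1.  Instead σ solves the truncated-Rayleigh
moment equation `E[m² | m ≤ t] = mean(m²)` at the observed threshold t,
then iterates with a widened threshold `t = 2σ̂` (better conditioned,
still below tissue intensities) to convergence.  On 192×192 images this
recovers σ within ~1–2 % per image.  Known limitation: when 2σ reaches
the lowest tissue intensities (σ ≳ half the minimum tissue signal) the
wide-threshold stage admits signal pixels and the estimate drifts high
(≈ +10 % at σ = 200 on the default phantom).

## Non-local means baseline

NLM replaces each pixel by a patch-similarity-weighted average over a
search window, weights `exp(−max(d² − 2σ̂², 0)/h²)`; the averaging is
delegated to scikit-image's exact (slow-mode) implementation.  Parameters
follow the reference protocol: h = 0.71, 5×5 patches, patch distance 6.
The dimensionless h is resolved against the noise amplitude,
`h_abs = 0.71·σ̂`: resolving it against the image range instead makes
same-image patch weights ≈1 across distinct tissues on piecewise-constant
anatomy, and NLM degenerates into a search-window mean that scores
*worse* than the noisy input at low σ — contradicting both its role as a
functioning baseline and the behaviour it is meant to reproduce.  With
σ̂ = 0 the weights collapse to a delta and NLM is the identity; with no
σ̂ at all the range-relative fallback applies.

## Synthetic phantoms

Real single-coil knee data and simulated brain volumes are access-gated,
so evaluation runs on generated phantoms designed to exercise exactly
what the methods need: piecewise-smooth anatomy (nested randomly
perturbed ellipses with per-tissue intensities spanning 400–2000
arbitrary units, peak fixed at 2000 so σ ∈ {50, 100, 200} spans
low/medium/high corruption), a smooth band-limited random phase field
(peak ~π/2) so the complex channels genuinely differ, and an exactly-zero
background outside the head ellipse sized so at least `background_margin`
of pixels are zero.  Slices are deterministic functions of
(seed, subject, slice).  What the phantoms do *not* model: MR contrast
physics (T1/T2/PD), coil sensitivities, partial-volume texture,
non-Gaussian artefacts.  Passing tests therefore demonstrate the
estimator/architecture contracts and the relative ordering of methods
under the stated noise model — not performance on real anatomy.

## Evaluation protocol

For each σ: noise is added to ground truth (fresh seeds, recorded),
per-σ networks are trained on the noisy training split, every method
denoises the noisy test slices, and MSE `Σ(I₁−I₂)²/(MN)`,
PSNR `10·log₁₀(MAX²/MSE)` and SSIM are computed against ground truth.
Metrics default to magnitude images with MAX = the test set's peak true
magnitude (a config switch selects complex-space metrics instead).  SSIM
uses a 7×7 Gaussian window (σ=1.5), C1=(0.01·MAX)², C2=(0.03·MAX)², and
the simplified two-factor form; the general (α, β, γ, C3) three-term
path is available and collapses to the simplified form at the defaults
(asserted to 1e-10).  Aggregation over slices/seeds is an unweighted
mean.  Two internal anchors guard the pipeline: the noisy row's
complex-space MSE must equal 2σ² per pixel (within MC error), and noisy
MSE must increase with σ.

Edge preservation is quantified as the mean gradient magnitude over a
one-pixel-dilated mask of true edges (gradient > 25 % of max); it
operationalises the qualitative observation that NLM trades edge/tissue
structure for noise removal while the blindspot posterior keeps the
observed pixel's weight at edges.

## Desk-scale problem sizes

The default quantitative run ("desk protocol") uses 16 subjects × one
64×64 slice (12 train / 4 test), depth-2 networks with 16 base features,
batches of 4, 30 epochs, Adam 3e-3 (10× the full-protocol rate for 10×
fewer epochs), σ ∈ {50, 100, 200}, scale 1/2000.  These sizes were chosen
so the whole protocol (six network trainings plus evaluation) completes
in a few minutes on one CPU; the full-scale protocol values remain the
config defaults.  At the lowest noise level (σ = 50) the 30-epoch SURE
net is close to break-even in magnitude-space MSE and its margin over the
noisy input varies with the training seed; the blindspot and NLM margins
are comfortable at all levels, and all methods win clearly at σ ≥ 100.
The edge-score gap between blindspot and the noise-relative NLM
parameterisation narrows at the extreme noise levels and its direction is
assessed under the protocol's seeded conditions.

## Numerical core

No deep-learning framework is used: the networks run on a compact
reverse-mode autodiff tape over float64 numpy arrays (convolution as one
GEMM per kernel tap, max-pool/upsample/rotation/padding ops, Adam).
Every operation's backward pass is verified against central finite
differences in the test suite.  Checkpoints are single `.npz` archives
holding a JSON architecture descriptor, ordered weights, the training
scale and σ.  Determinism: all randomness flows from explicit integer
seeds (numpy `default_rng`); training is bit-reproducible for a fixed
seed on a fixed BLAS.
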