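# Methods

## Acquisition model

A slice is a complex image `x` on an H×W grid. Acquisition through a Q-coil
array applies, per coil, the sensitivity map `Cq`, a centered orthonormal
2-D Fourier transform (DC at the grid center, `fftshift`-based; the
dominant convention in MRI), a binary trajectory mask `M`, and optional
circular complex Gaussian noise:

    yq = M (F(Cq x) + n)

Noise is injected in k-space (acquisition-domain noise) and calibrated by
power ratio: given a target noise level `NL ∈ [0, 1)`, the per-sample noise
variance is chosen so the expected noise power N satisfies
`NL = N / (N + S)` with S the measured mean power of the input. Masking is
applied after the noise so unacquired locations are exactly zero.

Coil maps are normalised at construction to `Σq |Cq|² = 1` at every pixel
(tolerance 1e-6). This makes the sensitivity-weighted combine
`Σq conj(Cq) xq` the exact left inverse of the coil projection, and the
zero-filled image `xu = Σq conj(Cq) F⁻¹(yq)` equal to the ground truth
under full sampling without noise (checked at 1e-8). The pipeline stays
complex double precision throughout; only the network boundary converts to
a 2-channel float32 real/imaginary representation. Magnitude images feed
the discriminators, the Sobel operator and all metrics.

## Sampling trajectories

All generators enforce their quota exactly and are deterministic in the
seed:

* **Gaussian 2-D** — `round(ρHW)` points drawn without replacement with
  probability proportional to a centered Gaussian density. The density
  width is `sigma_scale` × the grid half-extent; default 0.25, chosen to
  give visibly center-weighted masks over the 10–50 % range.
* **Gaussian 1-D** — `round(ρW)` whole phase-encode columns (axis
  configurable), Gaussian density over the line index. Note the point
  count `round(ρW)·H` can differ from `round(ρHW)` by rounding; the line
  quota is the contract for line masks.
* **Poisson-disc 2-D** — dart throwing over a shuffled pixel order with a
  local exclusion radius growing linearly from `min_radius_scale` pixels at
  the k-space center to 3× at the corner, then random trim/fill to
  `round(ρHW)`. The minimum-distance property holds for the pre-fill point
  set; the fill step (needed for exact quotas) may violate it.

An optional `center_fraction` forces a fully sampled calibration block; it
defaults to 0 (no such region is assumed).

## Synthetic data

Phantoms are real-valued images in [0, 1]: an outer "head" ellipse plus
random ellipses/annuli with pairwise intensity contrast ≥ 0.15, edge
transition width `edge_sharpness` (pixels; 0 = hard edges), and a smooth
multiplicative texture field. They emulate the piecewise-smooth,
edge-dense character of T1-weighted brain slices — enough structure for the
edge discriminator to have a real target — but not anatomy: no tissue
atlas, no B0/motion artefacts, no scanner noise statistics beyond the
k-space Gaussian model. Results on phantoms therefore demonstrate that the
pipeline optimises what it claims to optimise (holistic + edge fidelity
under a known forward model); they do not certify clinical image quality.

Coil maps are smooth Gaussian lobes centered at equispaced angles on a
circle just outside the field of view, with a gentle linear phase ramp per
coil and a small magnitude floor so pixelwise normalisation stays well
conditioned. The declared smoothness bound (max first difference of |Cq|)
is 0.1.

Dataset splits use largest-remainder rounding of the 5:2:3 ratio after a
seed-deterministic shuffle; 15360 slices split into 7680/3072/4608.

## Networks

The generator is a 4-level U-Net on 2-channel images. Each encoder level:
stride-2 3×3 conv → residual block (two 3×3 convs; a 1×1 shortcut conv iff
local residual learning is on) → frequency-channel-attention block. Each
decoder level: stride-2 transposed conv (k=4, exact 2× upsampling) →
skip concatenation with the same-scale encoder feature → two-conv fusion
without shortcut or attention (the decoder drops both to save compute).
Batch normalisation and leaky ReLU (slope 0.2) follow every conv except
final output layers. With global residual learning the network output is
added to its input, making the generator a refinement of the zero-filled
image; the two flags span the four ablation variants (GRLR, GRnLR, nGRLR,
nGRnLR) from one code path. Channel widths double per level from
`base_channels` (64 by default; 16 in the desk-scale configuration).

The FCA block squeezes an (N, C, H, W) feature map to length-C vectors by
partitioning channels into `n` equal groups and contracting each group
against the orthonormal 2-D DCT-II template of a preset frequency; the
first `n` frequencies in JPEG zigzag order are used, rebuilt per spatial
size so every index is valid at that scale. With `n = 1` and the DC index
the squeeze equals global average pooling × √(HW) — the squeeze-and-excite
special case, exposed as the `se` attention option. Two fully-connected
layers (reduce ×4, expand) and a logistic map produce per-channel weights
in (0, 1). Default `n = 16`, which must divide the channel count at every
attention site.

Both discriminators share one 11-conv-layer architecture on 1-channel
inputs (magnitudes for D₁, Sobel maps for D₂): six stride-2 3×3 convs, two
1×1 convs, a residual block of three 1×1 convs with identity shortcut, then
mean pooling over the remaining grid and a fully-connected layer with
logistic output. Mean-pool + FC keeps the head size-agnostic above the
64-pixel minimum implied by six halvings. Conv weights initialise
N(0, 0.02) from explicit seeds.

## Objective

Content losses are coil-wise sums of squared residuals (½‖·‖²): image
domain against the coil-projected ground truth, and frequency domain
separately on the acquired (`M`) and unacquired (`1−M`) k-space — the two
frequency terms sum exactly to the full k-space residual when noise is off
(disjoint support). The perceptual term compares magnitude images under a
pluggable feature extractor; the default is a fixed-seed untrained
two-layer conv stack (γ = 10 is matched to an inception-style extractor;
a VGG-style extractor pairs with γ = 0.0025). Batch losses are means of
per-sample values.

The adversarial term weights the holistic and edge discriminators by
μ = 0.6 and ν = 0.4. Discriminators maximise
`μ[log D₁(xt) − log D₁(x̂u)] + ν[log D₂(S(xt)) − log D₂(S(x̂u))]`; the
generator minimises the non-saturating form
`−μ log D₁(x̂u) − ν log D₂(S(x̂u))`, avoiding the vanishing-gradient
regime of the min–max value when discriminators are confident. Scores are
clamped to [1e-7, 1 − 1e-7] before logs. Setting μ = ν = 0 disables both
discriminators and reduces training to supervised content-loss fitting.

Total: `α·iMSE + β·(fMSE_M + fMSE_1−M) + γ·perceptual + adv`, with
α = 15, β = 0.1.

## Training

Each step performs one joint discriminator update (D₁ and D₂ through the
shared adversarial objective, generator output detached) followed by one
generator update on the total loss — a 1:1 update ratio. Adam uses
first-moment coefficient 0.5 (the GAN-stable setting) and β₂ = 0.999.
Learning rate: `max(1e-5, 1e-3 · 0.5^⌊epoch/5⌋)` for both players. Early
stopping triggers when the running minimum of validation NMSE has not
decreased for 8 consecutive epochs; it cannot fire before 8 epochs have
elapsed and is disabled for the ablation grid. Non-finite losses or
gradients abort the run rather than being skipped, surfacing instability
immediately. Runs are bit-deterministic in (seed, config, data) on fixed
thread settings; checkpoints store all weights and batch-norm running
statistics plus the embedded generator config, so save → load → validate
reproduces validation NMSE to 1e-10.

## Metrics

NMSE, PSNR and SSIM are computed on magnitude images normalised to the
reference peak, so PSNR uses peak = 1; exact equality returns the 100 dB
cap rather than infinity. SSIM uses the standard 11×11 Gaussian window
(σ = 1.5) with stabilisers (0.01)² and (0.03)². Edge-NMSE is the NMSE
between Sobel edge maps (3×3 kernels, replicate padding, no pre-smoothing)
and quantifies edge-domain fidelity; NMSE is per-slice. FID and expert
scoring are out of scope; `evaluate_pairs` accepts externally computed
scores through the report descriptors.

## Desk-scale study conditions

The reference experiments (in `edgegan.experiments`, used by the test
suite and the acceptance script) run at 64×64 with 4 coils and
`base_channels = 16`: the training benchmark uses 300 phantoms split
200/40/60, a Gaussian 2-D 30 % mask, batch 8 and 300 generator steps; the
ablation grid uses 40 training slices, two epochs per variant and three
seeds; the sampling-fraction trend averages zero-filled PSNR over five mask
seeds per fraction. These sizes were chosen so a single CPU completes each
experiment in minutes while leaving the qualitative contrasts (trained
reconstruction vs zero filling, global-residual vs plain variants,
quality vs sampling fraction) clearly resolved.

## Numerical choices and limitations

* The autodiff backend implements exactly the operators the networks need
  (im2col convolutions, transposed convs, batch norm, FFT with
  inverse-transform gradient, replicate-padded Sobel, DCT contraction);
  gradients are verified against central finite differences in the tests.
  float32 is used for network state, float64 for physics.
* Magnitude and Sobel-magnitude ops add a 1e-12 epsilon inside the square
  root for differentiability at zero.
* The zero-filled baseline on these phantoms is already strong
  (≈ 30 dB at 30 % sampling) because both the phantoms and the
  center-weighted masks are low-frequency dominated; gains over it are
  correspondingly conservative relative to what richer anatomy would show.
* Single-slice 2-D Cartesian acquisition only; no ESPIRiT-style
  sensitivity estimation (maps are known exactly by construction), no
  non-Cartesian or 3-D trajectories, no pretrained perceptual networks.
* How sensitivity maps would be obtained for real multi-coil archives is
  deliberately out of scope; the HDF5 layout stores maps explicitly.
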