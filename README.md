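# edgegan

Edge-enhanced dual-discriminator GAN reconstruction for undersampled
parallel-imaging MRI, with a complete simulated acquisition pipeline.

## The problem

MRI acquires data sequentially in k-space, so scan time scales with the
number of sampled spatial frequencies. Undersampling below the Nyquist rate
accelerates acquisition but produces aliasing artefacts in the zero-filled
reconstruction. With a multi-coil receive array the acquisition of a slice
*x* is

```
yq = M F (Cq ⊙ x) + n,          q = 1 … Q
```

where `Cq` is the complex sensitivity map of coil *q* (normalised so
`Σq |Cq|² = 1` pixelwise), `F` a centered orthonormal 2-D Fourier
transform, `M` a binary sampling trajectory and `n` complex Gaussian noise
with noise level `NL = N/(N+S)` (noise power over total power).

Most learned reconstruction methods optimise holistic image fidelity, which
tolerates over-smoothing; clinically decisive *edge* information degrades
first. This package reconstructs with a GAN whose generator — an improved
U-Net with frequency-channel attention and global/local residual learning —
is trained against **two** discriminators: `D₁` scores magnitude images,
`D₂` scores Sobel edge maps `S(·)`, so edge structure is adversarially
enforced alongside overall fidelity.

The generator refines the zero-filled image, `x̂u = G(xu) + xu`, and is
trained with

```
L = α·Σq ½‖xtq − Cq x̂u‖²                    (image-domain coil MSE)
  + β·( Σq ½‖yMq − M F Cq x̂u‖²              (acquired k-space MSE)
      + Σq ½‖y1−Mq − (1−M) F Cq x̂u‖² )      (unacquired k-space MSE)
  + γ·½‖f(xt) − f(x̂u)‖²                     (perceptual feature MSE)
  + Ladv(D₁, D₂; μ, ν)                       (dual adversarial term)
```

with defaults α = 15, β = 0.1, γ = 10, μ = 0.6 (holistic), ν = 0.4 (edge),
Adam with first-moment coefficient 0.5, learning rate 10⁻³ halved every 5
epochs down to 10⁻⁵, and early stopping after 8 epochs without validation
NMSE improvement.

No proprietary data is required: a synthetic-data module generates
piecewise-smooth brain-like phantoms, smooth complex coil maps emulating a
circular receive array, and 5:2:3 train/validation/test splits. Sampling
trajectories (Gaussian 2-D, Gaussian 1-D line masks, variable-density
Poisson-disc) hit their sampling quota exactly. The networks run on a small
numpy reverse-mode autodiff backend bundled with the package, so everything
trains on a plain CPU at desk scale.

## Worked example

```python
import numpy as np
from edgegan.synthetic import PhantomSpec, make_phantom, make_coilset, assemble_sample
from edgegan.trajectories import TrajectorySpec, gaussian2d_mask
from edgegan.evaluation import nmse, psnr, edge_nmse

phantom = make_phantom(PhantomSpec(shape=(64, 64), seed=7))
coils = make_coilset(64, 64, Q=4, seed=0)
mask = gaussian2d_mask(TrajectorySpec("gaussian2d", fraction=0.3, shape=(64, 64), seed=0))
sample = assemble_sample(phantom, coils, mask)

zf, gt = np.abs(sample.zero_filled), np.abs(sample.target)
peak = gt.max()
print(f"mask keeps {int(mask.data.sum())} of 4096 k-space samples "
      f"({100 * mask.achieved_fraction:.2f} %)")
print(f"zero-filled NMSE      = {nmse(zf, gt):.5f}")
print(f"zero-filled PSNR      = {psnr(zf / peak, gt / peak):.2f} dB")
print(f"zero-filled edge-NMSE = {edge_nmse(zf / peak, gt / peak):.4f}")
```

prints

```
mask keeps 1229 of 4096 k-space samples (30.00 %)
zero-filled NMSE      = 0.00414
zero-filled PSNR      = 29.83 dB
zero-filled edge-NMSE = 0.0338
```

The mask retains exactly round(0.3·64·64) = 1229 samples; the aliased
zero-filled image starts at 29.8 dB. Training the GAN at desk scale
(`edgegan.experiments.toy_training_benchmark`, 200 training phantoms,
4 coils, 300 generator steps) lifts held-out PSNR to 34.5 dB (+4.9 dB) and
cuts the edge-domain NMSE to about a fifth of the zero-filled value —
the edge discriminator's target quantity.

A CLI covers the full pipeline:

```bash
edgegan simulate --out data.h5 -n 100          # synthetic multi-coil HDF5
edgegan train --data data.h5 --out run/        # GAN training + checkpoints
edgegan reconstruct --checkpoint run/checkpoint.npz --data data.h5 --out recon.h5
edgegan evaluate --pred recon.h5 --out report  # NMSE/PSNR/SSIM/edge-NMSE
edgegan ablate --data data.h5 --out abl/       # GR/LR residual-learning grid
```

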