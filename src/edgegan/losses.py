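"""The complete training objective.

Content losses tie the reconstruction to the measurements in both domains:

* image-domain coil-projected MSE      ``Σ_q ½‖x_t^q − C^q x̂‖²``
* acquired-frequency MSE               ``Σ_q ½‖y_M^q − M F C^q x̂‖²``
* unacquired-frequency MSE             ``Σ_q ½‖y_{1−M}^q − (1−M) F C^q x̂‖²``
* perceptual feature MSE               ``½‖f(|x_t|) − f(|x̂|)‖²``

plus the dual-discriminator adversarial term with weights μ (holistic image)
and ν (edge map).  The generator minimises the non-saturating form
``−μ·log D₁(x̂) − ν·log D₂(S(x̂))``; the discriminators maximise
``μ[log D₁(x_t) − log D₁(x̂)] + ν[log D₂(S(x_t)) − log D₂(S(x̂))]``.

Total: ``α·iMSE + β·(fMSE_mask + fMSE_unmask) + γ·perceptual + adv``.

Every loss has two entry points: a plain-numpy path on single complex images
(used for evaluation and as the test oracle target) and a Tensor path on
2-channel batches (used in training, differentiable end to end).  The two
agree on a batch of one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, complex_mul_const, fft2c, magnitude, mask_mul
from .physics import CoilSet, SamplingMask, fourier

__all__ = [
    "LossWeights",
    "SCORE_EPS",
    "loss_imse",
    "loss_fmse_mask",
    "loss_fmse_unmask",
    "loss_perceptual",
    "loss_adversarial",
    "loss_total",
    "t_loss_imse",
    "t_loss_fmse_mask",
    "t_loss_fmse_unmask",
    "t_loss_perceptual",
    "t_loss_adversarial",
    "RandomConvExtractor",
    "identity_extractor",
]

SCORE_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the total objective.

    ``gamma`` defaults to the value matched to the inception-style
    perceptual extractor; a VGG-style extractor uses 0.0025 instead.
    """

    alpha: float = 15.0
    beta: float = 0.1
    gamma: float = 10.0
    mu: float = 0.6
    nu: float = 0.4

    GAMMA_INCEPTION = 10.0
    GAMMA_VGG = 0.0025

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.mu, self.nu) < 0:
            raise ValueError("all loss weights must be >= 0")

    @property
    def adversarial_enabled(self) -> bool:
        # mu = nu = 0 is the supervised degenerate configuration: both
        # discriminators (and their updates) are switched off entirely
        return self.mu + self.nu > 0


# ---------------------------------------------------------------------------
# numpy path (single complex image)
# ---------------------------------------------------------------------------


def _as_complex_image(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.complex128)
    if x.ndim != 2:
        raise ValueError(f"expected a single (H, W) image, got shape {x.shape}")
    return x


def loss_imse(x_hat: np.ndarray, coil_targets: np.ndarray, coils: CoilSet) -> float:
    """Image-domain coil-projected MSE of a reconstruction."""
    x_hat = _as_complex_image(x_hat)
    coil_targets = np.asarray(coil_targets, dtype=np.complex128)
    if coil_targets.shape != coils.maps.shape:
        raise ValueError(f"coil target shape {coil_targets.shape} != {coils.maps.shape}")
    diff = coil_targets - coils.maps * x_hat[None]
    return 0.5 * float(np.sum(np.abs(diff) ** 2))


def loss_fmse_mask(
    x_hat: np.ndarray, y: np.ndarray, coils: CoilSet, mask: SamplingMask
) -> float:
    """Acquired-frequency MSE against the masked measurements ``y_M^q``."""
    x_hat = _as_complex_image(x_hat)
    y = np.asarray(y, dtype=np.complex128)
    if y.shape != coils.maps.shape:
        raise ValueError(f"k-space shape {y.shape} != {coils.maps.shape}")
    m = mask.data.astype(np.float64)
    pred = m[None] * fourier(coils.maps * x_hat[None], "forward")
    diff = m[None] * y - pred
    return 0.5 * float(np.sum(np.abs(diff) ** 2))


def loss_fmse_unmask(
    x_hat: np.ndarray, kspace_full: np.ndarray, coils: CoilSet, mask: SamplingMask
) -> float:
    """Unacquired-frequency MSE against the fully sampled reference."""
    x_hat = _as_complex_image(x_hat)
    kspace_full = np.asarray(kspace_full, dtype=np.complex128)
    if kspace_full.shape != coils.maps.shape:
        raise ValueError(f"k-space shape {kspace_full.shape} != {coils.maps.shape}")
    m = 1.0 - mask.data.astype(np.float64)
    pred = m[None] * fourier(coils.maps * x_hat[None], "forward")
    diff = m[None] * kspace_full - pred
    return 0.5 * float(np.sum(np.abs(diff) ** 2))


def loss_perceptual(x_hat: np.ndarray, x_t: np.ndarray, extractor) -> float:
    """Feature-space MSE of the magnitude images under a fixed extractor."""
    a = extractor(np.abs(np.asarray(x_hat)))
    b = extractor(np.abs(np.asarray(x_t)))
    return 0.5 * float(np.sum((np.asarray(a) - np.asarray(b)) ** 2))


def _clamped_log(s: float) -> float:
    return float(np.log(np.clip(s, SCORE_EPS, 1.0 - SCORE_EPS)))


def loss_adversarial(
    d1_real: float, d1_fake: float, d2_real: float, d2_fake: float, weights: LossWeights
) -> tuple[float, float]:
    """Scalar adversarial terms (gen_term, disc_term) from mean scores.

    ``disc_term`` is the objective the discriminators maximise; ``gen_term``
    is the non-saturating loss the generator minimises.
    """
    for s in (d1_real, d1_fake, d2_real, d2_fake):
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"discriminator score {s} outside [0, 1]")
    mu, nu = weights.mu, weights.nu
    disc = mu * (_clamped_log(d1_real) - _clamped_log(d1_fake)) + nu * (
        _clamped_log(d2_real) - _clamped_log(d2_fake)
    )
    gen = -mu * _clamped_log(d1_fake) - nu * _clamped_log(d2_fake)
    return gen, disc


def loss_total(components: dict, weights: LossWeights):
    """Weighted total ``α·iMSE + β·(fM + f1-M) + γ·perceptual + adv_gen``.

    Works on floats and on Tensors alike. Missing components default to 0.
    """
    z = components.get
    return (
        weights.alpha * z("imse", 0.0)
        + weights.beta * (z("fmse_mask", 0.0) + z("fmse_unmask", 0.0))
        + weights.gamma * z("perceptual", 0.0)
        + z("adv_gen", 0.0)
    )


# ---------------------------------------------------------------------------
# Tensor path (2-channel batches, differentiable)
# ---------------------------------------------------------------------------


def _t_coil_project(x_hat: Tensor, coils: CoilSet) -> list[Tensor]:
    return [complex_mul_const(x_hat, coils.maps[q]) for q in range(coils.Q)]


def _t_half_sq(x: Tensor, n_batch: int) -> Tensor:
    return x.square().sum() * (0.5 / n_batch)


def t_loss_imse(x_hat: Tensor, coil_targets: np.ndarray, coils: CoilSet) -> Tensor:
    """Batch-mean image-domain coil-projected MSE.

    ``coil_targets`` is an (N, Q, H, W) complex array of ground-truth coil
    images; ``x_hat`` is the (N, 2, H, W) reconstruction.
    """
    N = x_hat.shape[0]
    total = None
    for q, proj in enumerate(_t_coil_project(x_hat, coils)):
        tgt = np.stack([coil_targets[:, q].real, coil_targets[:, q].imag], axis=1)
        term = _t_half_sq(proj - Tensor(tgt.astype(np.float32)), N)
        total = term if total is None else total + term
    return total


def _t_loss_fmse(
    x_hat: Tensor, kref: np.ndarray, coils: CoilSet, m: np.ndarray
) -> Tensor:
    N = x_hat.shape[0]
    total = None
    for q, proj in enumerate(_t_coil_project(x_hat, coils)):
        pred = mask_mul(fft2c(proj), m)
        ref = m[None] * kref[:, q]
        tgt = np.stack([ref.real, ref.imag], axis=1)
        term = _t_half_sq(pred - Tensor(tgt.astype(np.float32)), N)
        total = term if total is None else total + term
    return total


def t_loss_fmse_mask(
    x_hat: Tensor, kspace: np.ndarray, coils: CoilSet, mask: SamplingMask
) -> Tensor:
    return _t_loss_fmse(x_hat, kspace, coils, mask.data.astype(np.float64))


def t_loss_fmse_unmask(
    x_hat: Tensor, kspace_full: np.ndarray, coils: CoilSet, mask: SamplingMask
) -> Tensor:
    return _t_loss_fmse(x_hat, kspace_full, coils, 1.0 - mask.data.astype(np.float64))


def t_loss_perceptual(x_hat: Tensor, x_t: Tensor, extractor) -> Tensor:
    """Batch-mean feature-space MSE on magnitudes (differentiable)."""
    N = x_hat.shape[0]
    fa = extractor(magnitude(x_hat))
    fb = extractor(magnitude(x_t))
    if isinstance(fb, Tensor):
        fb = fb.detach()
    return _t_half_sq(fa - fb, N)


def _t_mean_log(s: Tensor) -> Tensor:
    return s.clamp(SCORE_EPS, 1.0 - SCORE_EPS).log().mean()


def t_loss_adversarial(
    d1_real: Tensor, d1_fake: Tensor, d2_real: Tensor, d2_fake: Tensor, weights: LossWeights
) -> tuple[Tensor, Tensor]:
    """Differentiable (gen_term, disc_term); expectations are batch means."""
    mu, nu = weights.mu, weights.nu
    disc = mu * (_t_mean_log(d1_real) - _t_mean_log(d1_fake)) + nu * (
        _t_mean_log(d2_real) - _t_mean_log(d2_fake)
    )
    gen = -mu * _t_mean_log(d1_fake) - nu * _t_mean_log(d2_fake)
    return gen, disc


# ---------------------------------------------------------------------------
# perceptual feature extractors
# ---------------------------------------------------------------------------


def identity_extractor(x):
    """Trivial extractor: features are the pixels themselves."""
    return x


class RandomConvExtractor(nn.Module):
    """Fixed-seed untrained two-layer conv feature map.

    A deterministic stand-in feature space for the perceptual loss: random
    (frozen) filters give a stable multi-scale projection of the magnitude
    image.  Accepts (N, 1, H, W) Tensors or a bare (H, W) numpy image.
    """

    def __init__(self, channels: int = 8, seed: int = 1234):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.c1 = nn.Conv2d(1, channels, 3, 2, 1, rng=rng)
        self.c2 = nn.Conv2d(channels, channels * 2, 3, 2, 1, rng=rng)
        for p in self.parameters():
            p.requires_grad = False

    def forward(self, x):
        if isinstance(x, np.ndarray):
            arr = np.asarray(x, dtype=np.float32)
            if arr.ndim == 2:
                arr = arr[None, None]
            with nn.no_grad():
                return self.forward(Tensor(arr)).data
        h = self.c1(x).leaky_relu(0.2)
        return self.c2(h).leaky_relu(0.2)
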