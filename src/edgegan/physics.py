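"""Parallel-imaging MRI acquisition model.

The acquisition of a single 2-D slice ``x`` through a ``Q``-coil receive array
is modelled as

    y^q = M ⊙ F(C^q ⊙ x) + n,    q = 1 … Q

where ``C^q`` is the complex sensitivity map of coil ``q``, ``F`` a centered
orthonormal 2-D Fourier transform, ``M`` a binary k-space sampling mask and
``n`` circular complex Gaussian noise.  With the maps normalised so that
``Σ_q |C^q|² = 1`` at every pixel, the sensitivity-weighted combine
``Σ_q conj(C^q) x^q`` is the exact left inverse of the coil projection, and
the zero-filled reconstruction ``x_u = Σ_q conj(C^q) F⁻¹(y^q)`` is the
adjoint of the full forward operator applied to the measurements.

Everything here stays complex double precision; conversion to the network's
two-channel real representation happens at the network boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoilSet",
    "SamplingMask",
    "NoiseSpec",
    "AcquiredSample",
    "fourier",
    "apply_sensitivity",
    "coil_combine",
    "add_noise",
    "forward_acquire",
    "zero_filled",
]

COIL_NORM_TOL = 1e-6


def _check_finite(a: np.ndarray, name: str = "input") -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")


def _check_2d(a: np.ndarray, name: str = "input") -> None:
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D grid, got shape {a.shape}")


@dataclass(frozen=True)
class CoilSet:
    """Q complex sensitivity maps, pixelwise normalised to unit SSoS.

    Parameters
    ----------
    maps : (Q, H, W) complex ndarray
        Must satisfy ``Σ_q |C^q(p)|² = 1`` at every pixel within 1e-6.
    """

    maps: np.ndarray

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=np.complex128)
        if maps.ndim != 3:
            raise ValueError(f"coil maps must be (Q, H, W), got {maps.shape}")
        _check_finite(maps, "coil maps")
        ssos = np.sum(np.abs(maps) ** 2, axis=0)
        if np.max(np.abs(ssos - 1.0)) > COIL_NORM_TOL:
            raise ValueError(
                "coil maps are not normalised: max |Σ|C|² - 1| = "
                f"{np.max(np.abs(ssos - 1.0)):.3g} > {COIL_NORM_TOL}"
            )
        object.__setattr__(self, "maps", maps)

    @property
    def Q(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


@dataclass(frozen=True)
class SamplingMask:
    """Binary k-space trajectory with an exact retained-sample quota.

    ``expected_ones`` is declared by the generator that built the mask: point
    trajectories retain ``round(ρ·H·W)`` samples, line trajectories retain
    ``round(ρ·W)`` whole phase-encode lines.
    """

    data: np.ndarray
    target_fraction: float
    expected_ones: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        _check_2d(data, "mask")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("mask must be binary")
        data = data.astype(np.uint8)
        if not (0.0 < self.target_fraction <= 1.0):
            raise ValueError(f"target_fraction must be in (0, 1], got {self.target_fraction}")
        expected = self.expected_ones
        if expected is None:
            expected = int(round(self.target_fraction * data.size))
        n_ones = int(data.sum())
        if n_ones != expected:
            raise ValueError(f"mask has {n_ones} ones, quota requires exactly {expected}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "expected_ones", expected)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def achieved_fraction(self) -> float:
        return float(self.data.mean())


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition noise specified as the power ratio NL = N / (N + S)."""

    nl: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.nl < 1.0):
            raise ValueError(f"noise level must be in [0, 1), got {self.nl}")


@dataclass(frozen=True)
class AcquiredSample:
    """One training sample: everything the reconstruction network consumes.

    Attributes
    ----------
    coil_images : (Q, H, W) complex — sensitivity-weighted ground truth x_t^q
    kspace : (Q, H, W) complex — acquired (masked, possibly noisy) y^q
    kspace_full : (Q, H, W) complex — fully sampled reference F(C^q x_t)
    target : (H, W) complex — combined ground truth x_t
    zero_filled : (H, W) complex — aliased network input x_u
    mask : SamplingMask
    """

    coil_images: np.ndarray
    kspace: np.ndarray
    kspace_full: np.ndarray
    target: np.ndarray
    zero_filled: np.ndarray
    mask: SamplingMask


def fourier(img: np.ndarray, direction: str = "forward") -> np.ndarray:
    """Centered orthonormal 2-D Fourier transform (DC at the grid center).

    The transform is unitary: image- and k-space energies agree (Parseval)
    and ``fourier(fourier(x), "inverse")`` recovers ``x`` to round-off.
    Applies over the last two axes, so coil stacks pass through unchanged.
    """
    img = np.asarray(img)
    _check_finite(img)
    if direction == "forward":
        return np.fft.fftshift(
            np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
            axes=(-2, -1),
        )
    if direction == "inverse":
        return np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
            axes=(-2, -1),
        )
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def apply_sensitivity(x: np.ndarray, coils: CoilSet) -> np.ndarray:
    """Project an image onto the coil array: ``x^q = C^q ⊙ x``.

    Returns a (Q, H, W) stack.  With normalised maps the per-pixel sum of
    squared magnitudes of the stack equals ``|x|²``.
    """
    x = np.asarray(x, dtype=np.complex128)
    _check_2d(x, "image")
    if x.shape != coils.shape:
        raise ValueError(f"image shape {x.shape} != coil map shape {coils.shape}")
    return coils.maps * x[None]


def coil_combine(imgs: np.ndarray, coils: CoilSet) -> np.ndarray:
    """Adjoint combine ``Σ_q conj(C^q) ⊙ x^q``; inverts apply_sensitivity."""
    imgs = np.asarray(imgs, dtype=np.complex128)
    if imgs.ndim != 3 or imgs.shape[0] != coils.Q:
        raise ValueError(f"expected {coils.Q} coil images of shape {coils.shape}, got {imgs.shape}")
    if imgs.shape[1:] != coils.shape:
        raise ValueError(f"coil image shape {imgs.shape[1:]} != map shape {coils.shape}")
    return np.sum(np.conj(coils.maps) * imgs, axis=0)


def add_noise(k: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Add circular complex Gaussian noise at a prescribed noise level.

    The per-sample noise variance is chosen so that the expected noise power
    N satisfies ``NL = N / (N + S)`` where S is the measured mean power of
    the input.  ``nl = 0`` returns the input untouched.
    """
    k = np.asarray(k, dtype=np.complex128)
    _check_finite(k, "k-space")
    if spec.nl == 0.0:
        return k.copy()
    signal_power = float(np.mean(np.abs(k) ** 2))
    noise_power = signal_power * spec.nl / (1.0 - spec.nl)
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(noise_power / 2.0)
    noise = rng.normal(0.0, sigma, k.shape) + 1j * rng.normal(0.0, sigma, k.shape)
    return k + noise


def forward_acquire(
    x: np.ndarray,
    coils: CoilSet,
    mask: SamplingMask,
    noise: NoiseSpec | None = None,
) -> np.ndarray:
    """Full forward model ``y^q = M ⊙ (F(C^q ⊙ x) + n)`` per coil.

    Noise is injected in k-space before masking, so masked-out locations are
    exactly zero in the output (acquisition only ever sees sampled points).
    """
    if mask.shape != coils.shape:
        raise ValueError(f"mask shape {mask.shape} != coil map shape {coils.shape}")
    coil_imgs = apply_sensitivity(x, coils)
    k = fourier(coil_imgs, "forward")
    if noise is not None and noise.nl > 0.0:
        k = add_noise(k, noise)
    return k * mask.data[None]


def zero_filled(y: np.ndarray, coils: CoilSet) -> np.ndarray:
    """Zero-filled reconstruction ``x_u = Σ_q conj(C^q) ⊙ F⁻¹(y^q)``."""
    y = np.asarray(y, dtype=np.complex128)
    if y.ndim != 3 or y.shape[0] != coils.Q:
        raise ValueError(f"expected {coils.Q} k-space grids, got shape {y.shape}")
    return coil_combine(fourier(y, "inverse"), coils)
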