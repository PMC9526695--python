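"""Differentiable image operations shared by the networks and losses."""

from __future__ import annotations

import numpy as np

from ..edge_ops import SOBEL_X, SOBEL_Y
from ..physics import fourier
from .autograd import Tensor
from .convops import conv2d, replicate_pad2d

__all__ = ["magnitude", "sobel_magnitude", "fft2c", "ifft2c", "complex_mul_const", "mask_mul"]

_EPS = 1e-12


def magnitude(x2ch: Tensor) -> Tensor:
    """Magnitude image |re + i·im| of a 2-channel (N, 2, H, W) tensor.

    Returns (N, 1, H, W); a small epsilon keeps the square root smooth at 0.
    """
    re = x2ch[:, 0:1]
    im = x2ch[:, 1:2]
    return (re.square() + im.square() + _EPS).sqrt()


_SOBEL_W = np.stack([SOBEL_X, SOBEL_Y]).astype(np.float32)[:, None]  # (2,1,3,3)


def sobel_magnitude(x: Tensor) -> Tensor:
    """Differentiable Sobel edge magnitude of a (N, 1, H, W) tensor.

    Matches :func:`edgegan.edge_ops.sobel` (replicate padding, 3×3 kernels)
    up to the smoothing epsilon in the magnitude.
    """
    w = Tensor(_SOBEL_W)
    g = conv2d(replicate_pad2d(x, 1), w, None, stride=1, pad=0)  # (N,2,H,W)
    return (g[:, 0:1].square() + g[:, 1:2].square() + _EPS).sqrt()


def _apply_centered_fft(data: np.ndarray, direction: str) -> np.ndarray:
    cdtype = np.complex128 if data.dtype == np.float64 else np.complex64
    z = data[:, 0].astype(cdtype) + 1j * data[:, 1].astype(cdtype)
    z = fourier(z, direction)
    return np.stack([z.real, z.imag], axis=1).astype(data.dtype)


def fft2c(x: Tensor) -> Tensor:
    """Centered orthonormal 2-D FFT of a 2-channel tensor.

    The transform is unitary, so the gradient is the inverse transform.
    """
    y = _apply_centered_fft(x.data, "forward")

    def bw(g):
        if x.requires_grad:
            x._accum(_apply_centered_fft(g, "inverse"))

    return Tensor._make(y, (x,), bw)


def ifft2c(x: Tensor) -> Tensor:
    y = _apply_centered_fft(x.data, "inverse")

    def bw(g):
        if x.requires_grad:
            x._accum(_apply_centered_fft(g, "forward"))

    return Tensor._make(y, (x,), bw)


def complex_mul_const(x: Tensor, c: np.ndarray) -> Tensor:
    """Multiply a 2-channel tensor by a fixed complex array (broadcastable)."""
    cr = Tensor(np.ascontiguousarray(c.real, dtype=np.float32))
    ci = Tensor(np.ascontiguousarray(c.imag, dtype=np.float32))
    re, im = x[:, 0:1], x[:, 1:2]
    from .autograd import concat

    return concat([re * cr - im * ci, re * ci + im * cr], axis=1)


def mask_mul(x: Tensor, mask: np.ndarray) -> Tensor:
    """Multiply both channels by a fixed real mask."""
    return x * Tensor(mask.astype(np.float32)[None, None])
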