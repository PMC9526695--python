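"""Convolution-family autodiff operations.

Convolutions are computed by explicit patch extraction (im2col) with the
kernel loop unrolled into strided slice copies, and reduced with batched
matmul; the scatter-add inverse (col2im) implements both the input gradient
of a convolution and the forward pass of a transposed convolution.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["conv2d", "conv_transpose2d", "batch_norm2d", "replicate_pad2d", "channel_contract"]


def _conv_out_size(H: int, k: int, s: int, p: int) -> int:
    return (H + 2 * p - k) // s + 1


def _im2col(xp: np.ndarray, k: int, s: int, Ho: int, Wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C, k, k, Ho, Wo) patches."""
    N, C = xp.shape[:2]
    cols = np.empty((N, C, k, k, Ho, Wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
    return cols

def _col2im(cols: np.ndarray, H: int, W: int, k: int, s: int, p: int) -> np.ndarray:
    """Scatter-add inverse of _im2col; returns (N, C, H, W)."""
    N, C = cols.shape[:2]
    Ho, Wo = cols.shape[-2:]
    out = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += cols[:, :, i, j]
    if p:
        out = out[:, :, p : p + H, p : p + W]
    return out


def _conv_forward(x: np.ndarray, w: np.ndarray, s: int, p: int) -> tuple[np.ndarray, np.ndarray]:
    N, C, H, W = x.shape
    O, _, k, _ = w.shape
    Ho, Wo = _conv_out_size(H, k, s, p), _conv_out_size(W, k, s, p)
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    cols = _im2col(xp, k, s, Ho, Wo)  # (N,C,k,k,Ho,Wo)
    cols2 = cols.reshape(N, C * k * k, Ho * Wo)
    y = (w.reshape(O, C * k * k) @ cols2).reshape(N, O, Ho, Wo)
    return y, cols2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D cross-correlation. x:(N,C,H,W), w:(O,C,k,k), b:(O,) optional."""
    N, C, H, W = x.data.shape
    O, Cw, k, _ = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    y, cols2 = _conv_forward(x.data, w.data, stride, pad)
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)
    Ho, Wo = y.shape[-2:]

    def bw(g):
        gy = g.reshape(N, O, Ho * Wo)
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", gy, cols2, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = (w.data.reshape(O, C * k * k).T @ gy).reshape(N, C, k, k, Ho, Wo)
            x._accum(_col2im(gcols, H, W, k, stride, pad))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(y, parents, bw)


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2, pad: int = 1
) -> Tensor:
    """Transposed convolution. x:(N,Cin,H,W), w:(Cin,Cout,k,k).

    Output spatial size is ``(H-1)*stride - 2*pad + k``; with k=4, stride=2,
    pad=1 this is an exact 2× upsampling.
    """
    N, Ci, H, W = x.data.shape
    Ciw, Co, k, _ = w.data.shape
    if Ciw != Ci:
        raise ValueError(f"conv_transpose2d channel mismatch: input {Ci}, weight {Ciw}")
    Ho = (H - 1) * stride - 2 * pad + k
    Wo = (W - 1) * stride - 2 * pad + k
    W2 = w.data.reshape(Ci, Co * k * k)
    cols = (W2.T @ x.data.reshape(N, Ci, H * W)).reshape(N, Co, k, k, H, W)
    y = _col2im(cols, Ho, Wo, k, stride, pad)
    if b is not None:
        y = y + b.data.reshape(1, Co, 1, 1)

    def bw(g):
        gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else g
        gcols = _im2col(gp, k, stride, H, W).reshape(N, Co * k * k, H * W)
        if x.requires_grad:
            x._accum((W2 @ gcols).reshape(N, Ci, H, W))
        if w.requires_grad:
            gw = np.einsum("nil,nkl->ik", x.data.reshape(N, Ci, H * W), gcols, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(y, parents, bw)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    Updates ``running_mean``/``running_var`` in place while training; uses
    them verbatim in eval mode so inference is deterministic.
    """
    N, C, H, W = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) / std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data[None, :, None, None]
            if training:
                gmean = gs.mean(axis=(0, 2, 3))
                gxhat_mean = (gs * xhat).mean(axis=(0, 2, 3))
                dx = (
                    gs
                    - gmean[None, :, None, None]
                    - xhat * gxhat_mean[None, :, None, None]
                ) / std[None, :, None, None]
            else:
                dx = gs / std[None, :, None, None]
            x._accum(dx)

    return Tensor._make(y, (x, gamma, beta), bw)


def replicate_pad2d(x: Tensor, pad: int = 1) -> Tensor:
    """Edge-replicate padding of the two trailing axes."""
    N, C, H, W = x.data.shape
    iy = np.clip(np.arange(-pad, H + pad), 0, H - 1)
    ix = np.clip(np.arange(-pad, W + pad), 0, W - 1)
    y = x.data[:, :, iy[:, None], ix[None, :]]

    def bw(g):
        if not x.requires_grad:
            return
        src = (iy[:, None] * W + ix[None, :]).ravel()
        gflat = g.reshape(N * C, -1)
        dx = np.zeros((N * C, H * W), dtype=g.dtype)
        np.add.at(dx, (np.arange(N * C)[:, None], src[None, :]), gflat)
        x._accum(dx.reshape(N, C, H, W))

    return Tensor._make(y, (x,), bw)


def channel_contract(x: Tensor, basis: np.ndarray) -> Tensor:
    """Per-channel spatial contraction: out[n,c] = Σ_hw x[n,c,h,w]·basis[c,h,w].

    ``basis`` is a fixed (C, H, W) array (e.g. per-channel DCT templates).
    """
    if basis.shape != x.data.shape[1:]:
        raise ValueError(f"basis shape {basis.shape} != feature shape {x.data.shape[1:]}")
    b = basis.astype(x.data.dtype)
    y = np.einsum("nchw,chw->nc", x.data, b, optimize=True)

    def bw(g):
        if x.requires_grad:
            x._accum(g[:, :, None, None] * b[None])

    return Tensor._make(y, (x,), bw)
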