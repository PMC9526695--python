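"""Autodiff backend: every operator's gradient is checked against central
finite differences, and the FFT/Sobel ops against their numpy references."""

import numpy as np
import pytest

from edgegan.edge_ops import sobel
from edgegan.nn import (
    Adam,
    Tensor,
    concat,
    conv2d,
    conv_transpose2d,
    fft2c,
    ifft2c,
    magnitude,
    no_grad,
    replicate_pad2d,
    sobel_magnitude,
)
from edgegan.nn.convops import batch_norm2d
from edgegan.physics import fourier


def numgrad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture
def rng64():
    return np.random.default_rng(7)


class TestConvGradients:
    def test_conv2d_gradients(self, rng64):
        x = rng64.normal(size=(2, 3, 6, 6))
        w = rng64.normal(size=(4, 3, 3, 3))
        b = rng64.normal(size=(4,))
        xt, wt, bt = Tensor(x, True), Tensor(w, True), Tensor(b, True)
        conv2d(xt, wt, bt, stride=2, pad=1).square().sum().backward()
        f = lambda: float((conv2d(Tensor(xt.data), Tensor(wt.data), Tensor(bt.data), 2, 1).data ** 2).sum())
        assert np.abs(xt.grad - numgrad(f, xt.data)).max() < 1e-6
        assert np.abs(wt.grad - numgrad(f, wt.data)).max() < 1e-6
        assert np.abs(bt.grad - numgrad(f, bt.data)).max() < 1e-6

    def test_conv_transpose_gradients_and_shape(self, rng64):
        x = rng64.normal(size=(2, 3, 5, 5))
        w = rng64.normal(size=(3, 2, 4, 4))
        xt, wt = Tensor(x, True), Tensor(w, True)
        y = conv_transpose2d(xt, wt, None, stride=2, pad=1)
        assert y.shape == (2, 2, 10, 10)  # exact 2x upsampling
        y.square().sum().backward()
        f = lambda: float((conv_transpose2d(Tensor(xt.data), Tensor(wt.data), None, 2, 1).data ** 2).sum())
        assert np.abs(xt.grad - numgrad(f, xt.data)).max() < 1e-6
        assert np.abs(wt.grad - numgrad(f, wt.data)).max() < 1e-6

    def test_batchnorm_gradients(self, rng64):
        x = rng64.normal(size=(3, 2, 4, 4))
        g0 = rng64.normal(size=(2,))
        b0 = rng64.normal(size=(2,))
        proj = rng64.normal(size=(3, 2, 4, 4))
        xt, gt, bt = Tensor(x, True), Tensor(g0, True), Tensor(b0, True)
        y = batch_norm2d(xt, gt, bt, np.zeros(2), np.ones(2), True)
        (y * Tensor(proj)).sum().backward()

        def f():
            yy = batch_norm2d(Tensor(xt.data), Tensor(gt.data), Tensor(bt.data),
                              np.zeros(2), np.ones(2), True)
            return float((yy.data * proj).sum())

        assert np.abs(xt.grad - numgrad(f, xt.data)).max() < 1e-5
        assert np.abs(gt.grad - numgrad(f, gt.data)).max() < 1e-6
        assert np.abs(bt.grad - numgrad(f, bt.data)).max() < 1e-6

    def test_replicate_pad_gradient(self, rng64):
        x = rng64.normal(size=(1, 2, 4, 4))
        proj = rng64.normal(size=(1, 2, 6, 6))
        xt = Tensor(x, True)
        (replicate_pad2d(xt, 1) * Tensor(proj)).sum().backward()
        f = lambda: float((replicate_pad2d(Tensor(xt.data), 1).data * proj).sum())
        assert np.abs(xt.grad - numgrad(f, xt.data)).max() < 1e-6


class TestElementwiseGradients:
    @pytest.mark.parametrize(
        "op",
        [
            lambda t: t.sigmoid(),
            lambda t: t.leaky_relu(0.2),
            lambda t: (t.square() + 1.0).sqrt(),
            lambda t: (t.square() + 0.5).log(),
            lambda t: t.exp(),
            lambda t: t.clamp(-0.5, 0.5),
        ],
    )
    def test_unary_ops(self, op, rng64):
        x = rng64.normal(size=(3, 4)) * 0.4 + 0.1
        xt = Tensor(x, True)
        op(xt).sum().backward()
        f = lambda: float(op(Tensor(xt.data)).data.sum())
        assert np.abs(xt.grad - numgrad(f, xt.data)).max() < 2e-5

    def test_matmul_and_broadcast_add(self, rng64):
        a = rng64.normal(size=(3, 4))
        b = rng64.normal(size=(4, 2))
        c = rng64.normal(size=(2,))
        at, bt, ct = Tensor(a, True), Tensor(b, True), Tensor(c, True)
        (at.matmul(bt) + ct).square().sum().backward()
        f = lambda: float(((at.data @ bt.data + ct.data) ** 2).sum())
        assert np.abs(at.grad - numgrad(f, at.data)).max() < 1e-6
        assert np.abs(ct.grad - numgrad(f, ct.data)).max() < 1e-6

    def test_concat_and_slice_gradients(self, rng64):
        a = rng64.normal(size=(2, 2, 3, 3))
        b = rng64.normal(size=(2, 1, 3, 3))
        at, bt = Tensor(a, True), Tensor(b, True)
        y = concat([at, bt], axis=1)
        y[:, 1:2].square().sum().backward()
        f = lambda: float((np.concatenate([at.data, bt.data], 1)[:, 1:2] ** 2).sum())
        assert np.abs(at.grad - numgrad(f, at.data)).max() < 1e-6
        assert np.abs(bt.grad - numgrad(f, bt.data)).max() < 1e-6


class TestSpectralOps:
    def test_fft_matches_physics_reference(self, rng64):
        z = rng64.normal(size=(8, 8)) + 1j * rng64.normal(size=(8, 8))
        x2 = np.stack([z.real, z.imag])[None]
        y = fft2c(Tensor(x2))
        ref = fourier(z, "forward")
        assert np.abs(y.data[0, 0] + 1j * y.data[0, 1] - ref).max() < 1e-10

    def test_fft_roundtrip_and_unitarity(self, rng64):
        x = rng64.normal(size=(2, 2, 8, 8))
        t = Tensor(x)
        back = ifft2c(fft2c(t))
        assert np.abs(back.data - x).max() < 1e-10
        assert abs((fft2c(t).data ** 2).sum() - (x**2).sum()) < 1e-8 * (x**2).sum()

    def test_fft_gradient_is_inverse_transform(self, rng64):
        x = rng64.normal(size=(1, 2, 8, 8))
        proj = rng64.normal(size=(1, 2, 8, 8))
        t = Tensor(x, True)
        (fft2c(t) * Tensor(proj)).sum().backward()
        f = lambda: float((fft2c(Tensor(t.data)).data * proj).sum())
        assert np.abs(t.grad - numgrad(f, t.data)).max() < 1e-6

    def test_sobel_magnitude_matches_reference(self, rng64):
        img = rng64.random((10, 10))
        out = sobel_magnitude(Tensor(img[None, None]))
        assert np.abs(out.data[0, 0] - sobel(img)).max() < 1e-5

    def test_magnitude_of_two_channel(self, rng64):
        z = rng64.normal(size=(1, 2, 4, 4))
        m = magnitude(Tensor(z))
        assert np.abs(m.data[0, 0] - np.hypot(z[0, 0], z[0, 1])).max() < 1e-6


class TestMachinery:
    def test_no_grad_blocks_graph(self):
        x = Tensor(np.ones((2, 2)), True)
        with no_grad():
            y = (x * 2.0).sum()
        assert y._backward is None and not y.requires_grad

    def test_adam_reduces_quadratic(self):
        w = Tensor(np.array([5.0, -3.0]), True)
        opt = Adam([w], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            loss = w.square().sum()
            loss.backward()
            opt.step()
        assert np.abs(w.data).max() < 0.05

    def test_adam_aborts_on_nonfinite_gradient(self):
        w = Tensor(np.array([1.0]), True)
        opt = Adam([w], lr=0.1)
        w.grad = np.array([np.nan])
        with pytest.raises(FloatingPointError):
            opt.step()
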