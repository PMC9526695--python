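"""Generator, discriminators and frequency-channel attention."""

import numpy as np
import pytest

from edgegan.networks import (
    Discriminator,
    DiscriminatorConfig,
    FCABlock,
    Generator,
    GeneratorConfig,
    dct2_basis,
    fca_squeeze,
    zigzag_indices,
)
from edgegan.nn import Tensor


class TestDCT:
    def test_zigzag_prefix(self):
        assert zigzag_indices(6) == [(0, 0), (0, 1), (1, 0), (2, 0), (1, 1), (0, 2)]

    def test_basis_orthonormality(self):
        idx = zigzag_indices(6, 8, 8)
        vecs = [dct2_basis(u, v, 8, 8).ravel() for u, v in idx]
        G = np.array([[a @ b for b in vecs] for a in vecs])
        assert np.abs(G - np.eye(6)).max() < 1e-12

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            dct2_basis(8, 0, 8, 8)


class TestFCASqueeze:
    def test_dc_squeeze_of_constant_channels(self):
        # constant c on an 8x8 grid: orthonormal DC coefficient = 8c
        f = np.full((1, 4, 8, 8), 3.0)
        v = fca_squeeze(f, 1, [(0, 0)])
        assert np.allclose(v, 24.0)

    def test_dc_squeeze_proportional_to_gap(self, rng):
        f = rng.normal(size=(2, 6, 8, 8))
        v = fca_squeeze(f, 1, [(0, 0)])
        gap = f.mean(axis=(2, 3))
        assert np.abs(v - 8.0 * gap).max() < 1e-6  # sqrt(64) * mean

    def test_basis_function_projects_to_unit(self):
        b01 = dct2_basis(0, 1, 8, 8)
        f = np.broadcast_to(b01, (1, 2, 8, 8)).copy()
        assert np.allclose(fca_squeeze(f, 1, [(0, 1)]), 1.0)
        assert np.abs(fca_squeeze(f, 1, [(0, 0)])).max() < 1e-12

    def test_group_partition_uses_distinct_frequencies(self):
        b01 = dct2_basis(0, 1, 8, 8)
        f = np.broadcast_to(b01, (1, 4, 8, 8)).copy()
        v = fca_squeeze(f, 2, [(0, 0), (0, 1)])
        assert np.abs(v[0, :2]).max() < 1e-12  # first group sees DC: zero
        assert np.allclose(v[0, 2:], 1.0)  # second group matches its basis

    def test_indivisible_group_count_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            fca_squeeze(np.zeros((1, 5, 8, 8)), 2, [(0, 0), (0, 1)])


class TestFCABlock:
    def test_shape_preserved_and_weights_bounded(self, rng):
        blk = FCABlock(8, 4)
        x = Tensor(rng.normal(size=(2, 8, 16, 16)).astype(np.float32))
        y = blk(x)
        assert y.shape == x.shape
        ratio = y.data / np.where(np.abs(x.data) > 1e-9, x.data, 1.0)
        assert (np.abs(y.data) <= np.abs(x.data) + 1e-6).all()  # weights in (0,1)
        del ratio

    def test_known_weight_scaling_contract(self, rng):
        # zero both FC layers, set expansion bias b: all channel weights are
        # sigmoid(b), so the block is exactly that scalar gain
        blk = FCABlock(4, 2)
        blk.fc1.weight.data[...] = 0
        blk.fc2.weight.data[...] = 0
        blk.fc2.bias.data[...] = 1.3
        x = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        y = blk(x)
        w = 1.0 / (1.0 + np.exp(-1.3))
        assert np.abs(y.data - w * x.data).max() < 1e-6

    def test_identical_channels_get_equal_weights(self, rng):
        blk = FCABlock(4, 1)  # one group: every channel squeezed identically
        base = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        x = Tensor(np.repeat(base, 4, axis=1))
        y = blk(x)
        scale = y.data / np.where(np.abs(x.data) > 1e-6, x.data, np.nan)
        scales = np.nanmean(scale, axis=(0, 2, 3))
        assert np.nanstd(scale) < 1e-5 or np.allclose(scales, scales[0], atol=1e-5)


@pytest.fixture(scope="module")
def small_cfg():
    return GeneratorConfig(base_channels=8, fca_n_frequencies=8)


@pytest.fixture(scope="module")
def D():
    return Discriminator(DiscriminatorConfig(base_channels=8), seed=0)


class TestGenerator:
    def test_shape_preserved(self, small_cfg, rng):
        G = Generator(small_cfg, seed=0)
        x = Tensor(rng.normal(size=(2, 2, 64, 64)).astype(np.float32))
        assert G(x).shape == (2, 2, 64, 64)

    def test_global_residual_identity_with_zeroed_head(self, small_cfg, rng):
        G = Generator(small_cfg, seed=0)
        G.out_conv.weight.data[...] = 0
        G.out_conv.bias.data[...] = 0
        G.eval()
        x = Tensor(rng.normal(size=(1, 2, 64, 64)).astype(np.float32))
        assert np.array_equal(G(x).data, x.data)

    def test_no_global_residual_zeroed_head_gives_zero(self, rng):
        cfg = GeneratorConfig(base_channels=8, fca_n_frequencies=8, use_global_residual=False)
        G = Generator(cfg, seed=0)
        G.out_conv.weight.data[...] = 0
        G.out_conv.bias.data[...] = 0
        G.eval()
        x = Tensor(rng.normal(size=(1, 2, 64, 64)).astype(np.float32))
        assert np.abs(G(x).data).max() == 0.0

    def test_indivisible_shape_rejected(self, small_cfg):
        G = Generator(small_cfg, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            G(Tensor(np.zeros((1, 2, 60, 60), dtype=np.float32)))

    def test_four_ablation_variants_from_two_flags(self):
        variants = {
            (gr, lr): Generator(
                GeneratorConfig(base_channels=8, fca_n_frequencies=8,
                                use_global_residual=gr, use_local_residual=lr),
                seed=0,
            )
            for gr in (True, False)
            for lr in (True, False)
        }
        assert len(variants) == 4
        # LR toggles the shortcut conv inside encoder residual blocks
        assert variants[(True, True)].down1.res.shortcut is not None
        assert variants[(True, False)].down1.res.shortcut is None

    def test_finite_gradients_through_generator(self, small_cfg, rng):
        G = Generator(small_cfg, seed=1)
        x = Tensor(rng.normal(size=(2, 2, 64, 64)).astype(np.float32))
        loss = G(x).square().sum()
        loss.backward()
        grads = [p.grad for p in G.parameters()]
        assert all(g is not None and np.all(np.isfinite(g)) for g in grads)

    def test_fca_divisibility_validated(self):
        with pytest.raises(ValueError, match="divide"):
            GeneratorConfig(base_channels=6, fca_n_frequencies=16)


class TestDiscriminator:
    def test_eleven_conv_layers(self):
        cfg = DiscriminatorConfig()
        assert cfg.conv_layers == 11

    def test_scores_strictly_inside_unit_interval(self, D, rng):
        x = Tensor(rng.random((3, 1, 64, 64)).astype(np.float32))
        s = D(x)
        assert s.shape == (3,)
        assert np.all(s.data > 0) and np.all(s.data < 1)

    def test_zeroed_head_scores_half(self, D, rng):
        D.fc.weight.data[...] = 0
        D.fc.bias.data[...] = 0
        s = D(Tensor(rng.random((2, 1, 64, 64)).astype(np.float32)))
        assert np.allclose(s.data, 0.5)

    def test_input_below_minimum_rejected(self, D):
        with pytest.raises(ValueError, match="minimum"):
            D(Tensor(np.zeros((1, 1, 32, 32), dtype=np.float32)))

    def test_finite_gradients(self, rng):
        D = Discriminator(DiscriminatorConfig(base_channels=8), seed=2)
        x = Tensor(rng.random((2, 1, 64, 64)).astype(np.float32))
        (-D(x).clamp(1e-7, 1 - 1e-7).log().mean()).backward()
        assert all(
            p.grad is None or np.all(np.isfinite(p.grad)) for p in D.parameters()
        )
        assert any(
            p.grad is not None and np.abs(p.grad).max() > 0 for p in D.parameters()
        )
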