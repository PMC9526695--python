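"""Objective terms: closed forms, decomposition identities, gradient flow."""

import numpy as np
import pytest

from edgegan.losses import (
    LossWeights,
    RandomConvExtractor,
    identity_extractor,
    loss_adversarial,
    loss_fmse_mask,
    loss_fmse_unmask,
    loss_imse,
    loss_perceptual,
    loss_total,
    t_loss_adversarial,
    t_loss_fmse_mask,
    t_loss_fmse_unmask,
    t_loss_imse,
    t_loss_perceptual,
)
from edgegan.nn import Tensor
from edgegan.physics import CoilSet, SamplingMask, fourier
from edgegan.synthetic import assemble_sample, make_coilset


@pytest.fixture(scope="module")
def tiny_setup():
    coils = make_coilset(8, 8, 2, seed=0)
    rng = np.random.default_rng(3)
    x_t = rng.random((8, 8))
    data = np.zeros((8, 8), dtype=np.uint8)
    data.flat[rng.choice(64, 19, replace=False)] = 1
    mask = SamplingMask(data, 19 / 64, expected_ones=19)
    sample = assemble_sample(x_t, coils, mask)
    return coils, mask, sample


class TestImageMSE:
    def test_zero_at_ground_truth(self, tiny_setup):
        coils, _, s = tiny_setup
        assert loss_imse(s.target, s.coil_images, coils) < 1e-12

    def test_constant_offset_closed_form(self):
        # Q=1, C≡1, x̂ = x_t + c on all N pixels -> ½·N·c²
        coils = CoilSet(np.ones((1, 4, 4), dtype=complex))
        x_t = np.zeros((4, 4), dtype=complex)
        c = 0.3
        val = loss_imse(x_t + c, np.stack([x_t]), coils)
        assert abs(val - 0.5 * 16 * c**2) < 1e-12

    def test_quadratic_scaling(self, tiny_setup, rng):
        coils, _, s = tiny_setup
        d = rng.random((8, 8))
        l1 = loss_imse(s.target + d, s.coil_images, coils)
        l2 = loss_imse(s.target + 2 * d, s.coil_images, coils)
        assert abs(l2 - 4 * l1) < 1e-8 * max(l2, 1)


class TestFrequencyMSE:
    def test_zero_at_ground_truth(self, tiny_setup):
        coils, mask, s = tiny_setup
        assert loss_fmse_mask(s.target, s.kspace, coils, mask) < 1e-12
        assert loss_fmse_unmask(s.target, s.kspace_full, coils, mask) < 1e-12

    def test_empty_mask_gives_zero(self, tiny_setup, rng):
        coils, _, s = tiny_setup
        empty = SamplingMask(np.zeros((8, 8), dtype=np.uint8), 0.01, expected_ones=0)
        x_hat = rng.random((8, 8))
        assert loss_fmse_mask(x_hat, np.zeros_like(s.kspace), coils, empty) == 0.0

    def test_full_mask_complement_gives_zero(self, tiny_setup, rng):
        coils, _, s = tiny_setup
        full = SamplingMask(np.ones((8, 8), dtype=np.uint8), 1.0)
        assert loss_fmse_unmask(rng.random((8, 8)), s.kspace_full, coils, full) == 0.0

    def test_naive_loop_oracle(self, tiny_setup, rng):
        coils, mask, s = tiny_setup
        x_hat = rng.random((8, 8))
        val = loss_fmse_mask(x_hat, s.kspace, coils, mask)
        acc = 0.0
        for q in range(coils.Q):
            pred = fourier(coils.maps[q] * x_hat, "forward")
            for i in range(8):
                for j in range(8):
                    if mask.data[i, j]:
                        acc += 0.5 * abs(s.kspace[q, i, j] - pred[i, j]) ** 2
        assert abs(val - acc) < 1e-10

    def test_disjoint_support_decomposition(self, tiny_setup, rng):
        # mask + complement partition k-space: the two frequency losses must
        # sum to the full k-space residual energy (no noise)
        coils, mask, s = tiny_setup
        x_hat = rng.random((8, 8))
        lm = loss_fmse_mask(x_hat, s.kspace, coils, mask)
        lu = loss_fmse_unmask(x_hat, s.kspace_full, coils, mask)
        full = 0.0
        for q in range(coils.Q):
            diff = s.kspace_full[q] - fourier(coils.maps[q] * x_hat, "forward")
            full += 0.5 * np.sum(np.abs(diff) ** 2)
        assert abs((lm + lu) - full) < 1e-8


class TestPerceptual:
    def test_zero_at_identity(self, tiny_setup):
        _, _, s = tiny_setup
        ext = RandomConvExtractor(seed=0)
        assert loss_perceptual(s.target, s.target, ext) == 0.0

    def test_identity_extractor_reduces_to_pixel_mse(self, tiny_setup, rng):
        _, _, s = tiny_setup
        x_hat = np.abs(s.target) + 0.1 * rng.random((8, 8))
        val = loss_perceptual(x_hat, s.target, identity_extractor)
        ref = 0.5 * np.sum((np.abs(x_hat) - np.abs(s.target)) ** 2)
        assert abs(val - ref) < 1e-10

    def test_fixed_seed_extractor_reproducible(self, tiny_setup, rng):
        _, _, s = tiny_setup
        x_hat = rng.random((8, 8))
        v1 = loss_perceptual(x_hat, s.target, RandomConvExtractor(seed=5))
        v2 = loss_perceptual(x_hat, s.target, RandomConvExtractor(seed=5))
        assert v1 == v2


class TestAdversarial:
    def test_symmetric_point_zero(self):
        gen, disc = loss_adversarial(0.5, 0.5, 0.5, 0.5, LossWeights())
        assert abs(disc) < 1e-12

    def test_single_discriminator_degenerate(self):
        w = LossWeights(mu=1.0, nu=0.0)
        gen, disc = loss_adversarial(0.9, 0.2, 0.123, 0.456, w)
        assert abs(disc - (np.log(0.9) - np.log(0.2))) < 1e-12
        assert abs(gen + np.log(0.2)) < 1e-12

    def test_hand_arithmetic_case(self):
        w = LossWeights(mu=0.6, nu=0.4)
        _, disc = loss_adversarial(0.9, 0.2, 0.8, 0.3, w)
        expected = 0.6 * (np.log(0.9) - np.log(0.2)) + 0.4 * (np.log(0.8) - np.log(0.3))
        assert abs(disc - expected) < 1e-12

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="score"):
            loss_adversarial(1.2, 0.5, 0.5, 0.5, LossWeights())

    def test_tensor_path_matches_scalar_path(self):
        w = LossWeights()
        g, d = loss_adversarial(0.9, 0.2, 0.8, 0.3, w)
        gt, dt = t_loss_adversarial(
            Tensor(np.array([0.9])), Tensor(np.array([0.2])),
            Tensor(np.array([0.8])), Tensor(np.array([0.3])), w,
        )
        assert abs(g - gt.item()) < 1e-6 and abs(d - dt.item()) < 1e-6


class TestTotal:
    def test_paper_default_weights(self):
        w = LossWeights()
        assert (w.alpha, w.beta, w.gamma, w.mu, w.nu) == (15.0, 0.1, 10.0, 0.6, 0.4)

    def test_reduces_to_gen_term_when_contents_zero(self):
        w = LossWeights()
        assert loss_total({"adv_gen": 1.7}, w) == 1.7

    def test_alpha_scales_only_image_term(self):
        comps = {"imse": 2.0, "fmse_mask": 1.0, "fmse_unmask": 1.0, "perceptual": 0.5, "adv_gen": 0.1}
        base = loss_total(comps, LossWeights(alpha=15))
        doubled = loss_total(comps, LossWeights(alpha=30))
        assert abs((doubled - base) - 15 * 2.0) < 1e-12

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1)


class TestTensorPathConsistency:
    def test_tensor_losses_match_numpy_on_batch_of_one(self, tiny_setup, rng):
        coils, mask, s = tiny_setup
        x_hat = rng.random((8, 8)) + 1j * 0.1 * rng.random((8, 8))
        xt = Tensor(np.stack([x_hat.real, x_hat.imag])[None].astype(np.float64))
        v_np = loss_imse(x_hat, s.coil_images, coils)
        v_t = t_loss_imse(xt, s.coil_images[None], coils).item()
        assert abs(v_np - v_t) < 1e-4 * max(1, v_np)
        v_np = loss_fmse_mask(x_hat, s.kspace, coils, mask)
        v_t = t_loss_fmse_mask(xt, s.kspace[None], coils, mask).item()
        assert abs(v_np - v_t) < 1e-4 * max(1, v_np)
        v_np = loss_fmse_unmask(x_hat, s.kspace_full, coils, mask)
        v_t = t_loss_fmse_unmask(xt, s.kspace_full[None], coils, mask).item()
        assert abs(v_np - v_t) < 1e-4 * max(1, v_np)

    def test_every_term_has_finite_nonzero_generator_gradient(self, tiny_setup, rng):
        coils, mask, s = tiny_setup
        xt = Tensor(rng.normal(size=(1, 2, 8, 8)), requires_grad=True)
        x_t_t = Tensor(np.stack([s.target.real, s.target.imag])[None])
        terms = {
            "imse": t_loss_imse(xt, s.coil_images[None], coils),
            "fmse_mask": t_loss_fmse_mask(xt, s.kspace[None], coils, mask),
            "fmse_unmask": t_loss_fmse_unmask(xt, s.kspace_full[None], coils, mask),
            "perceptual": t_loss_perceptual(xt, x_t_t, RandomConvExtractor(seed=2)),
        }
        for name, term in terms.items():
            xt.grad = None
            term.backward()
            assert xt.grad is not None, name
            assert np.all(np.isfinite(xt.grad)), name
            assert np.abs(xt.grad).max() > 0, name
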