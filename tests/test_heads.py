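"""Dual-decoder heads, PALM coupling, and the supervision losses."""

import numpy as np
import pytest

from amodalgrape.fixtures import make_scene
from amodalgrape.heads import (
    PALM,
    DualDecoderHead,
    FeaturePair,
    HeadConfig,
    incoherent_loss,
    mask_loss,
    palm_forward,
)
from amodalgrape.mask_core import laplacian_boundary
from amodalgrape.nn import Tensor
from conftest import oracle_bce, oracle_dice


class TestPALM:
    def test_output_shapes_equal_input_shapes(self):
        rng = np.random.default_rng(0)
        pair = FeaturePair(
            rng.standard_normal((2, 8, 4, 4)), rng.standard_normal((2, 8, 4, 4))
        )
        out = palm_forward(pair, rng_seed=1)
        assert out.f_m.shape == pair.f_m.shape
        assert out.f_i.shape == pair.f_i.shape

    def test_branch_weights_sum_to_one_everywhere(self):
        rng = np.random.default_rng(1)
        palm = PALM(8, rng=rng)
        pair = FeaturePair(
            rng.standard_normal((1, 8, 5, 5)), rng.standard_normal((1, 8, 5, 5))
        )
        palm(pair)
        w1, w2 = palm.last_weights
        assert np.allclose(w1 + w2, 1.0, atol=1e-6)

    def test_gradient_flows_across_branches(self):
        """A loss on the mask-branch output must reach the incoherent-branch
        input: the module exists to couple the two streams."""
        rng = np.random.default_rng(2)
        fm = Tensor(rng.standard_normal((1, 8, 4, 4)), requires_grad=True)
        fi = Tensor(rng.standard_normal((1, 8, 4, 4)), requires_grad=True)
        out = palm_forward(FeaturePair(fm, fi), rng_seed=3)
        out.f_m.square().mean().backward()
        assert fm.grad is not None and np.abs(fm.grad).max() > 0
        assert fi.grad is not None and np.abs(fi.grad).max() > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FeaturePair(np.zeros((1, 8, 4, 4)), np.zeros((1, 8, 5, 5)))

    def test_swap_equivariance_with_tied_weights(self):
        """With block-symmetric weights, swapping the two input branches
        swaps the two outputs."""
        rng = np.random.default_rng(4)
        c = 4
        palm = PALM(c, rng=rng)
        # Tie: phi_down invariant to input-block swap, phi_up emits equal
        # blocks, reduce invariant to block swap.
        wd = palm.phi_down.w.data
        wd[:, c:] = wd[:, :c]
        wu = palm.phi_up.w.data
        wu[c:] = wu[:c]
        wr = palm.reduce.w.data
        wr[:, c:] = wr[:, :c]
        a = rng.standard_normal((1, c, 5, 5))
        b = rng.standard_normal((1, c, 5, 5))
        out_ab = palm(FeaturePair(a.copy(), b.copy()))
        out_ba = palm(FeaturePair(b.copy(), a.copy()))
        assert np.allclose(out_ab.f_m.data, out_ba.f_i.data, atol=1e-5)
        assert np.allclose(out_ab.f_i.data, out_ba.f_m.data, atol=1e-5)


class TestDecodersForward:
    def test_default_output_resolutions(self):
        head = DualDecoderHead(channels=8)
        rng = np.random.default_rng(0)
        pred = head.forward(
            rng.standard_normal((2, 8, 14, 14)).astype(np.float32),
            rng.standard_normal((2, 8, 28, 28)).astype(np.float32),
        )
        assert pred.p_m.shape == (2, 28, 28)
        assert pred.p_i.shape == (2, 56, 56)

    def test_small_incoherent_output_variant(self):
        head = DualDecoderHead(channels=8, inc_out=28)
        rng = np.random.default_rng(0)
        pred = head.forward(
            rng.standard_normal((2, 8, 14, 14)).astype(np.float32),
            rng.standard_normal((2, 8, 28, 28)).astype(np.float32),
        )
        assert pred.p_i.shape == (2, 28, 28)

    def test_zero_features_give_finite_probabilities(self):
        head = DualDecoderHead(channels=8, use_palm=False)
        pred = head.forward(
            np.zeros((1, 8, 14, 14), np.float32), np.zeros((1, 8, 28, 28), np.float32)
        )
        for p in (pred.p_m, pred.p_i):
            assert np.isfinite(p).all()
            assert ((0 <= p) & (p <= 1)).all()

    def test_wrong_roi_size_rejected(self):
        head = DualDecoderHead(channels=8)
        with pytest.raises(ValueError):
            head.forward(
                np.zeros((1, 8, 16, 16), np.float32),
                np.zeros((1, 8, 28, 28), np.float32),
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            HeadConfig(inc_out=40)
        with pytest.raises(ValueError):
            HeadConfig(mask_roi=14, mask_out=30)
        with pytest.raises(ValueError):
            HeadConfig(supervision="contour")


class TestLosses:
    def test_mask_loss_at_hard_labels_is_tiny(self):
        rng = np.random.default_rng(0)
        t = (rng.random((8, 8)) > 0.5).astype(float)
        assert mask_loss(t, t) < 1e-5

    def test_mask_loss_at_uniform_half_is_ln_two(self):
        t = (np.random.default_rng(1).random((6, 6)) > 0.5).astype(float)
        assert mask_loss(np.full((6, 6), 0.5), t) == pytest.approx(np.log(2))

    def test_mask_loss_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random((4, 4))
            t = (rng.random((4, 4)) > 0.5).astype(float)
            assert mask_loss(p, t) == pytest.approx(oracle_bce(p, t), abs=1e-9)

    def test_incoherent_loss_optimum_is_near_zero(self):
        t = (np.random.default_rng(3).random((8, 8)) > 0.5).astype(float)
        assert incoherent_loss(t, t, t, 2.0) < 2e-2  # dice smoothing floor

    def test_incoherent_loss_zero_prediction_closed_form(self):
        t = np.zeros((6, 6))
        t.ravel()[:9] = 1.0  # S = 9
        got = incoherent_loss(np.zeros((6, 6)), t, np.zeros((6, 6)), 2.0)
        # dice = 1 - 1/(S+1); bce at clamped zero ~ (S/36) * -log(1e-7);
        # local term: dice(0,0) = 0, bce(0,0) = clamp floor only.
        expect = (
            (1 - 1 / 10)
            + oracle_bce(np.zeros(36), t.ravel())
            + 2.0 * oracle_bce(np.zeros(36), np.zeros(36))
        )
        assert got == pytest.approx(expect, rel=1e-9)

    def test_incoherent_loss_matches_two_term_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random((8, 8))
            t = (rng.random((8, 8)) > 0.5).astype(float)
            loc = ((rng.random((8, 8)) > 0.7) & (t > 0)).astype(float)
            expect = (
                oracle_dice(p, t)
                + oracle_bce(p, t)
                + 2.0 * (oracle_dice(p * loc, loc) + oracle_bce(p * loc, loc))
            )
            assert incoherent_loss(p, t, loc, 2.0) == pytest.approx(
                expect, abs=1e-9
            )

    def test_negative_lambda_rejected(self):
        z = np.zeros((4, 4))
        with pytest.raises(ValueError):
            incoherent_loss(z, z, z, -1.0)


class TestBoundarySupervisionVariant:
    def test_boundary_target_of_filled_square_is_perimeter(self):
        m = np.zeros((28, 28), bool)
        m[6:22, 6:22] = True
        b = laplacian_boundary(m)
        inner = m.copy()
        inner[7:21, 7:21] = False
        assert np.array_equal(b, inner)

    def test_switching_supervision_keeps_tensor_shapes(self):
        rng = np.random.default_rng(0)
        f_m = rng.standard_normal((1, 8, 14, 14)).astype(np.float32)
        f_i = rng.standard_normal((1, 8, 28, 28)).astype(np.float32)
        p_inc = DualDecoderHead(channels=8, supervision="incoherent").forward(f_m, f_i)
        p_bnd = DualDecoderHead(channels=8, supervision="boundary").forward(f_m, f_i)
        assert p_inc.p_m.shape == p_bnd.p_m.shape
        assert p_inc.p_i.shape == p_bnd.p_i.shape

    def test_boundary_no_palm_28_configuration_builds(self):
        head = DualDecoderHead(
            channels=8, supervision="boundary", use_palm=False, inc_out=28
        )
        pred = head.forward(
            np.zeros((1, 8, 14, 14), np.float32), np.zeros((1, 8, 28, 28), np.float32)
        )
        assert pred.p_i.shape == (1, 28, 28)


class TestTraining:
    def test_short_fit_reduces_loss_and_is_deterministic(self):
        scenes = [make_scene(3, 0.8, rng_seed=s, canvas_hw=(96, 96), scale=30)
                  for s in range(3)]
        head1 = DualDecoderHead(channels=8, n_iters=40, seed=5).fit(scenes)
        head2 = DualDecoderHead(channels=8, n_iters=40, seed=5).fit(scenes)
        assert head1.loss_history_ == head2.loss_history_
        assert np.mean(head1.loss_history_[-10:]) < np.mean(
            head1.loss_history_[:10]
        )

    def test_fit_without_usable_scenes_rejected(self):
        empty = make_scene(1, rng_seed=0)
        empty.visible_masks = [np.zeros_like(empty.label_map, dtype=bool)]
        with pytest.raises(ValueError):
            DualDecoderHead(channels=8, n_iters=5).fit([empty])
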