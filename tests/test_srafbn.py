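import numpy as np
import pytest

from srasnet import srafbn
from srasnet.srafbn import (SrConfig, SrForwardResult, SrModelState,
                            attention_weighted_loss, bicubic_upsample,
                            extract_shallow_features, feedback_step,
                            load_state, reconstruct_sr, save_state,
                            sr_forward, super_resolve, train_sr)

TINY = SrConfig(scale=2, n_iterations=2, n_groups=1, base_channels=8)


@pytest.fixture()
def tiny_state():
    return SrModelState(TINY, seed=0)


@pytest.fixture()
def lr_image():
    rng = np.random.default_rng(0)
    img = np.zeros((16, 12))
    img[3:13, 4:9] = rng.integers(40, 220, (10, 5))
    return img


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SrConfig(scale=5)
        with pytest.raises(ValueError):
            SrConfig(n_iterations=0)
        with pytest.raises(ValueError):
            SrConfig(loss_norm="huber")


class TestShallowFeatures:
    def test_zero_weights_give_zero_features(self, tiny_state, lr_image):
        tiny_state.zero_all_weights()
        l0, _ = extract_shallow_features(lr_image, tiny_state)
        assert (l0 == 0).all()

    def test_spatial_dims_preserved(self, tiny_state, lr_image):
        l0, _ = extract_shallow_features(lr_image, tiny_state)
        assert l0.shape == (1, TINY.base_channels, 16, 12)

    def test_constant_input_gives_constant_maps(self, tiny_state):
        # interior pixels see identical stencils on a constant image
        img = np.full((16, 16), 80.0)
        l0, _ = extract_shallow_features(img, tiny_state)
        interior = l0[0, :, 2:-2, 2:-2]
        assert np.allclose(interior, interior[:, :1, :1], atol=1e-4)

    def test_undersized_input_rejected(self, tiny_state):
        with pytest.raises(ValueError):
            extract_shallow_features(np.zeros((4, 4)), tiny_state)


class TestFeedbackBlock:
    def test_zero_weights_give_zero_output(self, tiny_state, lr_image):
        l0, _ = extract_shallow_features(lr_image, tiny_state)
        tiny_state.zero_all_weights()
        out, _ = feedback_step(l0, l0, tiny_state)
        assert (out == 0).all()

    def test_deterministic(self, tiny_state, lr_image):
        l0, _ = extract_shallow_features(lr_image, tiny_state)
        a, _ = feedback_step(l0, l0, tiny_state)
        b, _ = feedback_step(l0, l0, tiny_state)
        assert np.array_equal(a, b)

    def test_single_group_equals_hand_composition(self, tiny_state, lr_image):
        """With one mapping group the block is exactly
        fuse -> encode -> decode -> reduce."""
        l0, _ = extract_shallow_features(lr_image, tiny_state)
        out, _ = feedback_step(l0, l0, tiny_state)
        s = tiny_state
        h0, _ = s.fb_in.forward(np.concatenate([l0, l0], axis=1))
        e, _ = s.enc_reduce[0].forward(h0)
        e, _ = s.enc_conv[0].forward(e)
        e, _ = s.relu.forward(e)
        d, _ = s.dec_reduce[0].forward(e)
        d, _ = s.dec_conv[0].forward(d)
        d, _ = s.relu.forward(d)
        manual, _ = s.fb_out.forward(d)
        assert np.allclose(out, manual)

    def test_misaligned_inputs_rejected(self, tiny_state, lr_image):
        l0, _ = extract_shallow_features(lr_image, tiny_state)
        with pytest.raises(ValueError):
            feedback_step(l0[:, :, :8], l0, tiny_state)


class TestReconstruction:
    def test_zero_weights_reduce_to_bicubic(self, tiny_state, lr_image):
        tiny_state.zero_all_weights()
        l0, _ = extract_shallow_features(lr_image, tiny_state)
        res, sr = reconstruct_sr(l0, lr_image, tiny_state)
        assert np.allclose(res, 0)
        assert np.allclose(sr, bicubic_upsample(lr_image, 2))

    def test_sr_minus_upsample_equals_residual(self, tiny_state, lr_image):
        l0, _ = extract_shallow_features(lr_image, tiny_state)
        fb, _ = feedback_step(l0, l0, tiny_state)
        res, sr = reconstruct_sr(fb, lr_image, tiny_state)
        assert np.allclose(sr - bicubic_upsample(lr_image, 2), res)

    @pytest.mark.parametrize("scale", [2, 3, 4])
    def test_output_dims_scale_with_factor(self, lr_image, scale):
        cfg = SrConfig(scale=scale, n_iterations=1, n_groups=1,
                       base_channels=4)
        state = SrModelState(cfg, seed=1)
        out = super_resolve(lr_image, state)
        assert out.shape == (16 * scale, 12 * scale)


class TestForward:
    def test_one_image_per_iteration(self, tiny_state, lr_image):
        result = sr_forward(lr_image, tiny_state)
        assert len(result.sr_images) == TINY.n_iterations
        assert all(sr.shape == (32, 24) for sr in result.sr_images)

    def test_single_iteration_equals_manual_composition(self, lr_image):
        cfg = SrConfig(scale=2, n_iterations=1, n_groups=1, base_channels=8)
        state = SrModelState(cfg, seed=3)
        result = sr_forward(lr_image, state)
        l0, _ = extract_shallow_features(lr_image, state)
        fb, _ = feedback_step(l0, l0, state)
        _, sr = reconstruct_sr(fb, lr_image, state)
        assert np.allclose(result.final, sr)

    def test_zero_weight_network_is_bicubic_every_iteration(self, tiny_state,
                                                            lr_image):
        tiny_state.zero_all_weights()
        result = sr_forward(lr_image, tiny_state)
        up = bicubic_upsample(lr_image, 2)
        for sr in result.sr_images:
            assert np.allclose(sr, up)

    def test_parameter_count_independent_of_iterations(self):
        def n_params(iters):
            s = SrModelState(SrConfig(scale=2, n_iterations=iters,
                                      n_groups=2, base_channels=8))
            # attention logits are the only per-iteration parameters
            return sum(p.data.size for p in s.parameters()) - iters
        assert n_params(1) == n_params(4) == n_params(7)


class TestLoss:
    def test_perfect_reconstruction_gives_zero(self, tiny_state, lr_image):
        hr = bicubic_upsample(lr_image, 2)
        result = SrForwardResult([hr.copy(), hr.copy()], [None, None], hr)
        assert attention_weighted_loss(result, hr, tiny_state) == 0.0

    def test_uniform_weights_average_the_losses(self, tiny_state):
        hr = np.zeros((8, 8))
        sr1 = np.full((8, 8), 2.0)   # L1 loss 2
        sr2 = np.full((8, 8), 4.0)   # L1 loss 4
        result = SrForwardResult([sr1, sr2], [None, None], hr)
        assert attention_weighted_loss(result, hr, tiny_state) == \
            pytest.approx(3.0)

    def test_attention_weights_form_probability_vector(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            state = SrModelState(TINY, seed=0)
            state.attn_logits.data[...] = rng.normal(0, 3, 2)
            w = state.attention_weights()
            assert (w >= 0).all()
            assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_dim_mismatch_rejected(self, tiny_state, lr_image):
        result = sr_forward(lr_image, tiny_state)
        with pytest.raises(ValueError):
            attention_weighted_loss(result, np.zeros((10, 10)), tiny_state)


class TestTraining:
    def test_loss_decreases_on_tiny_problem(self, sr_pairs):
        train_pairs, _ = sr_pairs
        state, history = train_sr(train_pairs[:10], TINY, seed=1, epochs=4)
        assert history[-1] < history[0]

    def test_constant_image_pairs_converge_toward_zero_loss(self):
        lr = np.full((10, 10), 100, dtype=np.uint8)
        hr = np.full((20, 20), 100, dtype=np.uint8)
        state, history = train_sr([(lr, hr)] * 4, TINY, seed=0, epochs=10)
        # bicubic of a constant is the constant, so loss starts ~0 and the
        # best-epoch state must keep it there
        assert min(history) < 0.5

    def test_deterministic_per_seed(self, sr_pairs):
        train_pairs, _ = sr_pairs
        _, h1 = train_sr(train_pairs[:5], TINY, seed=7, epochs=2)
        _, h2 = train_sr(train_pairs[:5], TINY, seed=7, epochs=2)
        assert h1 == h2

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError):
            train_sr([], TINY)

    def test_checkpoint_roundtrip_bit_identical(self, tmp_path, sr_pairs,
                                                lr_image):
        train_pairs, _ = sr_pairs
        state, _ = train_sr(train_pairs[:5], TINY, seed=2, epochs=1)
        save_state(state, tmp_path / "m.ckpt")
        loaded = load_state(tmp_path / "m.ckpt")
        a = sr_forward(lr_image, state).final
        b = sr_forward(lr_image, loaded).final
        assert np.array_equal(a, b)


class TestSuperResolve:
    def test_zero_weight_state_is_clamped_bicubic(self, tiny_state, lr_image):
        tiny_state.zero_all_weights()
        out = super_resolve(lr_image, tiny_state)
        assert np.allclose(out, np.clip(bicubic_upsample(lr_image, 2), 0, 255))

    def test_output_in_valid_range(self, tiny_state, lr_image):
        out = super_resolve(lr_image, tiny_state)
        assert out.min() >= 0 and out.max() <= 255
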