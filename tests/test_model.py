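"""Architecture-level tests: shapes, thresholds, residual identity,
parameter accounting, checkpoints and the analytic gradient."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegshrink import ConfigError, ModelConfig
from eegshrink.model import (
    InvalidThresholdError, ShapeError, TRAINABLE_KEYS,
    basefe_forward, count_parameters, forward_batch, init_params,
    load_checkpoint, model_forward, param_shapes, rsbu_forward,
    save_checkpoint, se_thresholds, soft_threshold, zero_params,
)
from eegshrink.train import _batch_loss_and_grads


class TestSoftThreshold:
    @pytest.mark.parametrize("x,tau,expected", [
        (2.0, 0.5, 1.5),       # positive branch: y = x - tau
        (0.3, 0.5, 0.0),       # dead zone |x| <= tau
        (-2.0, 0.5, -1.5),     # negative branch: y = x + tau
        (1.7, 0.0, 1.7),       # zero threshold is the identity
        (0.5, 0.5, 0.0),       # boundary belongs to the dead zone
    ])
    def test_branch_table(self, x, tau, expected):
        assert soft_threshold(np.array(x), tau) == pytest.approx(expected)

    def test_negative_tau_rejected(self):
        with pytest.raises(InvalidThresholdError):
            soft_threshold(np.ones(3), -0.1)

    def test_per_channel_broadcast(self):
        x = np.array([[2.0, -2.0], [2.0, -2.0]])
        tau = np.array([[0.5], [1.5]])
        out = soft_threshold(x, tau)
        assert np.allclose(out, [[1.5, -1.5], [0.5, -0.5]])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=30),
           st.floats(0, 10))
    def test_never_increases_magnitude(self, xs, tau):
        x = np.array(xs)
        y = soft_threshold(x, tau)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)
        assert np.all(np.sign(y) * np.sign(x) >= 0)


class TestSEThresholds:
    def test_zero_params_give_sigma_half(self, tiny_config):
        params = zero_params(tiny_config)
        U = np.tile([2.0, -2.0, 2.0, -2.0], (tiny_config.n_filters, 1))
        sigma, tau = se_thresholds(U, params, "CW")
        assert np.allclose(sigma, 0.5)
        assert np.allclose(tau, 1.0)   # 0.5 * mean(|2,-2,2,-2|)

    def test_zero_feature_map_gives_zero_tau(self, tiny_config):
        params = init_params(tiny_config, seed=0)
        U = np.zeros((tiny_config.n_filters, 7))
        _, tau = se_thresholds(U, params, "CW")
        assert np.allclose(tau, 0.0)
        _, tau_cs = se_thresholds(U, params, "CS")
        assert tau_cs == pytest.approx(0.0)

    def test_bound_over_random_draws(self, tiny_config):
        """tau_r is sigma_r * mean|U_r| with sigma in (0,1), so it can
        never exceed the channel's mean absolute activation."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            params = init_params(tiny_config, seed=int(rng.integers(2**31)))
            U = rng.standard_normal((tiny_config.n_filters, 12)) * 3
            sigma, tau = se_thresholds(U, params, "CW")
            bound = np.abs(U).mean(axis=1)
            assert np.all(tau >= 0) and np.all(tau <= bound + 1e-12)
            # independent recomputation of the threshold formula
            assert np.allclose(tau, sigma * bound)

    def test_cs_mode_scalar(self, tiny_config):
        params = init_params(tiny_config, seed=1)
        U = np.random.default_rng(2).standard_normal((4, 9))
        sigma, tau = se_thresholds(U, params, "CS")
        assert np.ndim(sigma) == 0 and np.ndim(tau) == 0
        assert 0 <= tau <= np.abs(U).mean() + 1e-12


class TestBaseFE:
    def test_output_shape_default(self):
        cfg = ModelConfig()
        params = init_params(cfg, seed=0)
        I = basefe_forward(np.zeros(384), cfg, params)
        assert I.shape == (32, 192)

    def test_zero_epoch_zero_output(self):
        cfg = ModelConfig()
        params = init_params(cfg, seed=0)
        params["conv_b"][:] = 0.0   # zero shift end to end
        I = basefe_forward(np.zeros(384), cfg, params)
        assert np.allclose(I, 0.0)

    def test_against_naive_convolution(self, tiny_config):
        """Interior outputs match a direct O(n*k) convolution loop,
        batch-norm bypassed (identity affine, unit running stats) so the
        comparison isolates the convolution + Softshrink."""
        cfg = tiny_config
        params = init_params(cfg, seed=3)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(cfg.input_len)
        I = basefe_forward(x, cfg, params)

        lam = cfg.softshrink_lambda
        xp = np.pad(x, cfg.conv_pad)
        eps = 1e-5
        for f in range(cfg.n_filters):
            for t in range(cfg.feature_len):
                acc = params["conv_b"][f]
                for k in range(cfg.conv_kernel):
                    acc += params["conv_w"][f, k] * xp[t * cfg.conv_stride + k]
                acc = acc / np.sqrt(1 + eps)   # BN with running stats (0, 1)
                expected = np.sign(acc) * max(abs(acc) - lam, 0.0)
                assert I[f, t] == pytest.approx(expected, abs=1e-9)

    def test_wrong_length_rejected(self, tiny_config):
        params = init_params(tiny_config, seed=0)
        with pytest.raises(ShapeError):
            basefe_forward(np.zeros(17), tiny_config, params)


class TestRSBU:
    def test_zeroed_block_is_identity(self, tiny_config):
        params = zero_params(tiny_config)
        I = np.random.default_rng(0).standard_normal(
            (tiny_config.n_filters, 10))
        U, sigma, tau, O, P = rsbu_forward(I, params, tiny_config)
        assert np.allclose(U, 0) and np.allclose(O, 0)
        assert np.array_equal(P, I)

    def test_residual_identity_exact(self, tiny_config):
        params = init_params(tiny_config, seed=4)
        I = np.random.default_rng(1).standard_normal(
            (tiny_config.n_filters, 10))
        U, _, _, O, P = rsbu_forward(I, params, tiny_config)
        assert np.array_equal(P, I + O)

    def test_shrinkage_sparsifies(self, tiny_config):
        """Soft thresholding can only create zeros, never remove them."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            params = init_params(tiny_config, seed=int(rng.integers(2**31)))
            I = rng.standard_normal((tiny_config.n_filters, 16))
            U, _, _, O, _ = rsbu_forward(I, params, tiny_config)
            assert (O == 0).mean() >= (U == 0).mean()
            assert np.all(np.abs(O) <= np.abs(U) + 1e-12)

    def test_channel_mismatch_rejected(self, tiny_config):
        params = init_params(tiny_config, seed=0)
        with pytest.raises(ShapeError):
            rsbu_forward(np.zeros((tiny_config.n_filters + 1, 8)),
                         params, tiny_config)


class TestModelForward:
    def test_trace_shapes_default(self):
        cfg = ModelConfig()
        params = init_params(cfg, seed=0)
        t = model_forward(np.random.default_rng(0).standard_normal(384),
                          cfg, params)
        assert t.basefe_out.shape == (32, 192)
        assert t.rsbu_out.shape == (32, 192)
        assert t.gap.shape == (32,)
        assert t.logits.shape == (2,)
        assert t.probabilities.shape == (2,)

    def test_probabilities_normalised(self, tiny_config):
        params = init_params(tiny_config, seed=0)
        X = np.random.default_rng(3).standard_normal(
            (1000, tiny_config.input_len))
        probs = forward_batch(X, params, tiny_config)["probs"]
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_gap_is_temporal_mean(self, tiny_config):
        params = init_params(tiny_config, seed=2)
        t = model_forward(np.random.default_rng(0).standard_normal(
            tiny_config.input_len), tiny_config, params)
        assert np.allclose(t.gap, t.rsbu_out.mean(axis=1), atol=1e-12)

    def test_logit_dot_product_oracle(self, tiny_config):
        """Logits equal sum_k w_{k,c} m_k^g + b_c by an explicit loop."""
        rng = np.random.default_rng(11)
        params = init_params(tiny_config, seed=6)
        for _ in range(50):
            t = model_forward(rng.standard_normal(tiny_config.input_len),
                              tiny_config, params)
            for c in range(tiny_config.n_classes):
                acc = params["head_b"][c]
                for k in range(tiny_config.n_filters):
                    acc += params["head_w"][k, c] * t.gap[k]
                assert t.logits[c] == pytest.approx(acc, abs=1e-6)

    def test_eval_mode_bit_deterministic(self, tiny_config):
        params = init_params(tiny_config, seed=0)
        x = np.random.default_rng(9).standard_normal(tiny_config.input_len)
        t1 = model_forward(x, tiny_config, params)
        t2 = model_forward(x, tiny_config, params)
        assert np.array_equal(t1.probabilities, t2.probabilities)
        assert np.array_equal(t1.rsbu_out, t2.rsbu_out)

    def test_threshold_bounds_in_trace(self, tiny_config):
        params = init_params(tiny_config, seed=8)
        t = model_forward(np.random.default_rng(2).standard_normal(
            tiny_config.input_len), tiny_config, params)
        bound = np.abs(t.pre_threshold).mean(axis=1)
        assert np.all(t.tau >= 0) and np.all(t.tau <= bound + 1e-12)
        assert np.all((t.sigma > 0) & (t.sigma < 1))

    def test_nonfinite_input_rejected(self, tiny_config):
        params = init_params(tiny_config, seed=0)
        x = np.zeros(tiny_config.input_len)
        x[3] = np.nan
        with pytest.raises(FloatingPointError):
            model_forward(x, tiny_config, params)


class TestParameterCount:
    def test_front_end_alone(self):
        """Conv 1*32*64+32 plus BN 2*32 = 2,144 scalars."""
        shapes = param_shapes(ModelConfig())
        front = sum(int(np.prod(shapes[k])) for k in
                    ("conv_w", "conv_b", "bn0_gamma", "bn0_beta"))
        assert front == 2144

    def test_head_alone(self):
        shapes = param_shapes(ModelConfig())
        head = sum(int(np.prod(shapes[k])) for k in ("head_w", "head_b"))
        assert head == 66

    def test_full_default_cw(self):
        assert count_parameters(ModelConfig()) == 5554

    def test_cs_variant_smaller(self):
        cw = count_parameters(ModelConfig(threshold_mode="CW"))
        cs = count_parameters(ModelConfig(threshold_mode="CS"))
        # CS restore layer maps 16 -> 1 instead of 16 -> 32
        assert cw - cs == 16 * 31 + 31

    def test_count_matches_actual_arrays(self, tiny_config):
        params = init_params(tiny_config, seed=0)
        total = sum(params[k].size for k in TRAINABLE_KEYS)
        assert total == count_parameters(tiny_config)


class TestConfigValidation:
    def test_se_reduction_must_divide(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_filters=32, se_reduction=5)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(softshrink_lambda=-0.1)

    def test_feature_len_formula(self):
        cfg = ModelConfig()
        assert cfg.feature_len == (384 + 2 * 31 - 64) // 2 + 1 == 192


class TestCheckpoint:
    def test_roundtrip(self, tiny_config, tmp_path):
        params = init_params(tiny_config, seed=5)
        save_checkpoint(tmp_path / "ck.npz", params, tiny_config)
        loaded, cfg = load_checkpoint(tmp_path / "ck.npz")
        assert cfg == tiny_config
        for k, v in params.items():
            assert np.array_equal(loaded[k], v)

    def test_shape_mismatch_detected(self, tiny_config, tmp_path):
        params = init_params(tiny_config, seed=5)
        params["head_w"] = params["head_w"][:2]
        save_checkpoint(tmp_path / "bad.npz", params, tiny_config)
        with pytest.raises(ShapeError):
            load_checkpoint(tmp_path / "bad.npz")


class TestGradients:
    @pytest.mark.parametrize("mode", ["CW", "CS"])
    def test_backprop_matches_finite_differences(self, mode):
        """The hand-written backward pass agrees with central finite
        differences on every parameter tensor (spot-checked entries)."""
        cfg = ModelConfig(input_len=32, conv_kernel=8, conv_stride=2,
                          conv_pad=3, n_filters=4, se_reduction=2,
                          dropout_p=0.3, threshold_mode=mode)
        rng0 = np.random.default_rng(7)
        X = rng0.standard_normal((5, 32))
        y = np.array([0, 1, 1, 0, 1])
        base = init_params(cfg, seed=1)

        def loss_at(params):
            rng = np.random.default_rng(99)   # fixed dropout draw
            out = forward_batch(X, params, cfg, training=True, rng=rng,
                                capture=True)
            return _batch_loss_and_grads(out, y, params, cfg, 0.1)

        _, grads = loss_at({k: v.copy() for k, v in base.items()})
        eps = 1e-6
        pick = np.random.default_rng(0)
        for key in TRAINABLE_KEYS:
            gk = grads[key]
            for flat in pick.choice(gk.size, size=min(3, gk.size),
                                    replace=False):
                ix = np.unravel_index(flat, gk.shape)
                pp = {k: v.copy() for k, v in base.items()}
                pp[key][ix] += eps
                pm = {k: v.copy() for k, v in base.items()}
                pm[key][ix] -= eps
                num = (loss_at(pp)[0] - loss_at(pm)[0]) / (2 * eps)
                # loose denominator floor: kinks in ReLU/shrinkage make
                # tiny gradients noisy under finite differences
                denom = max(1e-4, abs(num), abs(gk[ix]))
                assert abs(num - gk[ix]) / denom < 1e-3, key
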