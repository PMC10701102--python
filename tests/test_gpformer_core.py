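import math

import numpy as np
import pytest

from gpformer import (
    GPformer,
    ModelConfig,
    autocorrelation_attention,
    autocorrelation_scores,
    gelu,
    gelu_tanh,
    positional_encoding,
    series_decomposition,
    topk_delays,
)
from gpformer.nn.autograd import Tensor
from gpformer.train import focal_mae_loss


def brute_force_circular_correlation(q, k):
    L = len(q)
    return np.array(
        [sum(q[(s + tau) % L] * k[s] for s in range(L)) for tau in range(L)]
    )


class TestPositionalEncoding:
    def test_t_zero_alternates_sin_cos(self):
        np.testing.assert_allclose(positional_encoding([0], 4)[0], [0, 1, 0, 1])

    def test_unit_position_smallest_frequency(self):
        pe = positional_encoding([1], 2)[0]
        np.testing.assert_allclose(pe, [math.sin(1), math.cos(1)], atol=1e-12)

    def test_values_bounded(self):
        pe = positional_encoding(np.array([0, 17, 99_999_937]), 16)
        assert np.all(np.abs(pe) <= 1.0)

    def test_column_period(self):
        # component 2k has period 2*pi/omega_k in t
        d, k = 8, 1
        omega = 1.0 / 10000 ** (2 * k / d)
        period = 2 * math.pi / omega
        t = np.array([3.0, 3.0 + period])
        pe = positional_encoding(t, d)
        assert pe[0, 2 * k] == pytest.approx(pe[1, 2 * k], abs=1e-9)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError, match="even"):
            positional_encoding([1, 2], 5)


class TestAutocorrelationScores:
    def test_impulse(self):
        e = np.array([1.0, 0, 0, 0])
        np.testing.assert_allclose(autocorrelation_scores(e, e), [1, 0, 0, 0], atol=1e-12)

    def test_all_ones(self):
        ones = np.ones(4)
        np.testing.assert_allclose(autocorrelation_scores(ones, ones), [4, 4, 4, 4], atol=1e-12)

    @pytest.mark.parametrize("L", [4, 16, 64])
    def test_fft_matches_brute_force(self, L):
        rng = np.random.default_rng(L)
        q, k = rng.standard_normal(L), rng.standard_normal(L)
        np.testing.assert_allclose(
            autocorrelation_scores(q, k),
            brute_force_circular_correlation(q, k),
            atol=1e-8,
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            autocorrelation_scores(np.ones(4), np.ones(5))


class TestTopkDelays:
    def test_k_is_floor_of_c_log_l(self):
        delays, weights = topk_delays(np.array([1.0, 3.0, 2.0, 0.0]), c=1.0, L=4)
        assert delays.shape == (1,)  # floor(ln 4) = 1
        np.testing.assert_allclose(weights, [1.0])
        assert delays[0] == 1

    def test_softmax_over_selected_scores(self):
        delays, weights = topk_delays(np.array([3.0, 1.0, 2.0, 0.0]), c=2.0, L=4)
        np.testing.assert_array_equal(delays, [0, 2])  # k = floor(2 ln 4) = 2
        np.testing.assert_allclose(weights, [0.73105858, 0.26894142], atol=1e-7)
        assert weights.sum() == pytest.approx(1.0)

    def test_ties_break_toward_smaller_lag(self):
        delays, _ = topk_delays(np.array([5.0, 2.0, 5.0, 5.0]), c=2.0, L=4)
        np.testing.assert_array_equal(delays, [0, 2])

    def test_all_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            topk_delays(np.full(4, np.nan), c=1.0, L=4)


class TestAttention:
    def test_dominant_zero_lag_returns_value(self):
        # an impulse autocorrelates only at lag 0, so with k=1 output == v
        rng = np.random.default_rng(0)
        q = np.zeros((1, 8, 2))
        q[0, 0, :] = 1.0
        v = rng.standard_normal((1, 8, 2))
        out = autocorrelation_attention(q, q, v, c=0.4)  # k = 1
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_output_is_convex_combination_of_rolls(self):
        rng = np.random.default_rng(1)
        q = rng.standard_normal((2, 16, 3))
        v = rng.standard_normal((2, 16, 3))
        out = autocorrelation_attention(q, q, v, c=2.0)
        # rolling by L is the identity, so norms stay bounded by max roll norm
        assert np.all(np.abs(out) <= np.abs(v).max() + 1e-12)

    def test_tensor_path_matches_numpy_reference(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 20, 4))
        cfg = ModelConfig(d_model=4, c_factor=2.0, decomp_window=3, dropout=0.0)
        model = GPformer(cfg, 20, seed=0)
        t = Tensor(x)
        out_t = model._attention(t, t, t).data
        out_np = autocorrelation_attention(x, x, x, c=2.0)
        np.testing.assert_allclose(out_t, out_np, atol=1e-10)


class TestSeriesDecomposition:
    def test_constant_input_zero_residual(self):
        res, trend = series_decomposition(np.full(4, 5.0), window=3)
        np.testing.assert_allclose(res, np.zeros(4))
        np.testing.assert_allclose(trend, np.full(4, 5.0))

    def test_hand_computed_moving_average(self):
        res, trend = series_decomposition(np.array([1.0, 2, 3, 4]), window=3)
        np.testing.assert_allclose(trend, [4 / 3, 2, 3, 11 / 3])
        np.testing.assert_allclose(res, [-1 / 3, 0, 0, 1 / 3])

    def test_conserves_input_exactly(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 33))
        for w in (1, 5, 25):
            res, trend = series_decomposition(x, window=w)
            np.testing.assert_allclose(res + trend, x, rtol=0, atol=1e-14)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            series_decomposition(np.ones(8), window=4)

    def test_tensor_moving_average_matches_reference(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 15, 3))
        _, trend = series_decomposition(x, window=5, axis=1)
        np.testing.assert_allclose(Tensor(x).moving_average(5).data, trend, atol=1e-12)


class TestGelu:
    def test_zero(self):
        assert gelu(0.0) == 0.0

    def test_tanh_approximation_printed_value(self):
        assert gelu_tanh(1.0) == pytest.approx(0.841192, abs=1e-6)

    def test_exact_and_approx_agree(self):
        x = np.linspace(-4, 4, 101)
        np.testing.assert_allclose(gelu(x), gelu_tanh(x), atol=2e-3)

    def test_asymptotically_identity(self):
        assert gelu(20.0) / 20.0 == pytest.approx(1.0, abs=1e-12)


class TestNetwork:
    @pytest.fixture
    def small_model(self):
        cfg = ModelConfig(d_model=8, n_blocks=2, decomp_window=5, dropout=0.0)
        return GPformer(cfg, n_markers=24, positions=np.arange(24) * 1000, seed=1)

    def test_forward_shape_and_determinism(self, small_model):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((6, 1, 24))
        p1 = small_model.predict(x)
        p2 = small_model.predict(x)
        assert p1.shape == (6,)
        np.testing.assert_array_equal(p1, p2)  # eval mode is bit-identical

    def test_batch_permutation_equivariance(self, small_model):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((5, 1, 24))
        perm = np.array([3, 0, 4, 1, 2])
        np.testing.assert_allclose(
            small_model.predict(x[perm]), small_model.predict(x)[perm], atol=1e-9
        )

    def test_head_linearity(self, small_model):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((4, 1, 24))
        base = small_model.predict(x)
        bias = small_model.b_head.data.copy()
        small_model.W_head.data *= 2.0
        doubled = small_model.predict(x)
        np.testing.assert_allclose(doubled - bias, 2.0 * (base - bias), atol=1e-9)

    def test_layernorm_statistics_inside_block(self):
        rng = np.random.default_rng(8)
        x = Tensor(rng.standard_normal((3, 10, 16)))
        ln = x.layer_norm()
        np.testing.assert_allclose(ln.data.mean(axis=-1), 0.0, atol=1e-12)
        np.testing.assert_allclose(ln.data.var(axis=-1), 1.0, atol=1e-3)

    def test_wrong_channel_count_rejected(self, small_model):
        with pytest.raises(ValueError, match="channels"):
            small_model.predict(np.zeros((2, 3, 24)))

    def test_wrong_length_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.predict(np.zeros((2, 1, 30)))

    def test_kgm_config_expects_concatenated_channels(self):
        cfg = ModelConfig(d_model=4, decomp_window=3, use_kgm=True, base_encoding="onehot")
        assert cfg.in_channels == 6
        model = GPformer(cfg, 10, seed=0)
        out = model.predict(np.zeros((2, 6, 10)))
        assert out.shape == (2,)

    def test_dropout_only_in_training_mode(self):
        cfg = ModelConfig(d_model=8, decomp_window=5, dropout=0.5)
        model = GPformer(cfg, 16, seed=2)
        x = np.random.default_rng(9).standard_normal((4, 1, 16))
        eval_pred = model.predict(x)
        train_pred = model.forward(x, rng=np.random.default_rng(0)).data
        assert not np.allclose(eval_pred, train_pred)

    def test_checkpoint_round_trip(self, tmp_path, small_model):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((3, 1, 24))
        path = tmp_path / "model.npz"
        small_model.save(path)
        loaded = GPformer.load(path)
        np.testing.assert_array_equal(loaded.predict(x), small_model.predict(x))
        assert loaded.cfg == small_model.cfg

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(11)
        cfg = ModelConfig(d_model=4, decomp_window=3, dropout=0.0)
        model = GPformer(cfg, 12, seed=3)
        x = rng.standard_normal((3, 1, 12))
        y = rng.standard_normal(3)
        loss = focal_mae_loss(y, model.forward(x))
        loss.backward()

        def central_diff(flat, i, eps):
            old = flat[i]
            flat[i] = old + eps
            lp = focal_mae_loss(y, model.forward(x)).item()
            flat[i] = old - eps
            lm = focal_mae_loss(y, model.forward(x)).item()
            flat[i] = old
            return (lp - lm) / (2 * eps)

        checked = 0
        for p in model.parameters():
            flat, gflat = p.data.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                num1 = central_diff(flat, i, 1e-6)
                num2 = central_diff(flat, i, 1e-7)
                # hard top-k lag selection makes the loss piecewise smooth;
                # skip points where the difference quotient itself is unstable
                if abs(num1 - num2) > 1e-3 * (abs(num1) + abs(num2) + 1e-8):
                    continue
                assert gflat[i] == pytest.approx(num1, rel=1e-4, abs=1e-8)
                checked += 1
        assert checked >= 15

    def test_gradients_finite_on_random_batch(self, small_model):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((4, 1, 24))
        y = rng.standard_normal(4)
        loss = focal_mae_loss(y, small_model.forward(x))
        loss.backward()
        for p in small_model.parameters():
            assert np.all(np.isfinite(p.grad))


class TestModelConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"d_model": 7},
            {"d_model": 0},
            {"decomp_window": 4},
            {"dropout": 1.0},
            {"c_factor": 0.0},
            {"base_encoding": "hex"},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)
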