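"""Sequence model: convolution primitives, attention variants, residual
blocks, causality, and gradient correctness of the hand-written backprop."""

import logging

import numpy as np
import pytest

from capwave import (
    ModelConfig,
    TCNAttention,
    ValidationError,
    causal_dilated_conv,
    chomp,
    min_layers,
    mse_loss,
    receptive_field,
)
from capwave.model.layers import ChannelAttention, ResidualBlock, TemporalAttention


def direct_sum_conv(x, f, d):
    """O(N*k) reference: F(n) = sum_i f(i) x(n - d*i), zero for negative t."""
    out = np.zeros(len(x))
    for n in range(len(x)):
        for i in range(len(f)):
            j = n - d * i
            if j >= 0:
                out[n] += f[i] * x[j]
    return out


class TestConvPrimitives:
    @pytest.mark.parametrize("x,f,d,expected", [
        ([1, 2, 3, 4], [1, 1], 1, [1, 3, 5, 7]),
        ([1, 2, 3, 4], [1, 1], 2, [1, 2, 4, 6]),
        ([5, -1, 2], [1], 7, [5, -1, 2]),  # k=1 identity for any dilation
    ])
    def test_worked_examples(self, x, f, d, expected):
        np.testing.assert_allclose(causal_dilated_conv(x, f, d), expected)

    def test_matches_direct_sum_on_random_instances(self, rng):
        for _ in range(25):
            k = int(rng.integers(1, 6))
            d = int(rng.integers(1, 9))
            x = rng.normal(size=int(rng.integers(2, 50)))
            f = rng.normal(size=k)
            np.testing.assert_allclose(causal_dilated_conv(x, f, d),
                                       direct_sum_conv(x, f, d), atol=1e-9)

    def test_validation(self):
        with pytest.raises(ValidationError):
            causal_dilated_conv([1, 2], [1, 1], 0)
        with pytest.raises(ValidationError):
            causal_dilated_conv([1, 2], [], 1)

    def test_chomp(self):
        np.testing.assert_array_equal(chomp([1, 2, 3, 4], 1), [1, 2, 3])
        np.testing.assert_array_equal(chomp([1, 2, 3, 4], 0), [1, 2, 3, 4])
        with pytest.raises(ValidationError):
            chomp([1, 2], 3)


class TestReceptiveField:
    @pytest.mark.parametrize("k,L,expected", [(2, 4, 16), (3, 1, 3), (7, 0, 1)])
    def test_closed_form(self, k, L, expected):
        assert receptive_field(k, L) == expected

    @pytest.mark.parametrize("k,L", [(2, 1), (2, 3), (3, 2), (5, 2)])
    def test_closed_form_equals_dependency_count(self, k, L):
        # impulse probing through the composed all-ones conv stack: the last
        # output is influenced by exactly R input positions
        n = receptive_field(k, L) + 5
        count = 0
        for j in range(n):
            x = np.zeros(n)
            x[j] = 1.0
            for level in range(L):
                x = causal_dilated_conv(x, np.ones(k), 2 ** level)
            count += x[-1] != 0
        assert count == receptive_field(k, L)

    @pytest.mark.parametrize("N,k,expected", [(16, 2, 4), (1, 9, 0), (1024, 2, 10)])
    def test_min_layers(self, N, k, expected):
        assert min_layers(N, k) == expected
        assert receptive_field(k, expected) >= N

    def test_validation(self):
        with pytest.raises(ValidationError):
            receptive_field(0, 2)
        with pytest.raises(ValidationError):
            min_layers(16, 1)


class TestAttention:
    def test_zeroed_channel_gate_halves_activations(self, rng):
        attn = ChannelAttention(4, 2, np.random.default_rng(0))
        for p in attn.params():
            p.value[...] = 0.0
        z = rng.normal(size=(4, 20))
        np.testing.assert_allclose(attn.forward(z), z / 2.0, atol=1e-12)

    @pytest.mark.parametrize("cls", [ChannelAttention, TemporalAttention])
    def test_shape_preserved(self, cls, rng):
        layer = (cls(5, 2, np.random.default_rng(0)) if cls is ChannelAttention
                 else cls(5, np.random.default_rng(0)))
        z = rng.normal(size=(5, 33))
        assert layer.forward(z).shape == z.shape

    @pytest.mark.parametrize("cls", [ChannelAttention, TemporalAttention])
    def test_last_step_perturbation_is_invisible_earlier(self, cls, rng):
        layer = (cls(3, 1, np.random.default_rng(0)) if cls is ChannelAttention
                 else cls(3, np.random.default_rng(0)))
        z = rng.normal(size=(3, 16))
        base = layer.forward(z)
        z2 = z.copy()
        z2[:, -1] += 5.0
        out = layer.forward(z2)
        np.testing.assert_array_equal(base[:, :-1], out[:, :-1])

    def test_invalid_reduction_rejected(self):
        with pytest.raises(ValidationError):
            ChannelAttention(4, 0, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            ModelConfig(attention_reduction=0)


class TestResidualBlock:
    def test_zero_branch_reduces_to_relu_identity(self, rng):
        block = ResidualBlock(3, 3, 2, 2, 0.0, "channel", 2,
                              np.random.default_rng(0))
        for layer in (block.conv1, block.conv2, block.attn):
            for p in layer.params():
                p.value[...] = 0.0
        x = rng.normal(size=(3, 30))
        np.testing.assert_allclose(block.forward(x), np.maximum(x, 0.0), atol=1e-12)

    @pytest.mark.parametrize("k,level", [(2, 0), (3, 2), (5, 1)])
    def test_length_preserved(self, k, level, rng):
        block = ResidualBlock(2, 4, k, 2 ** level, 0.0, "channel", 4,
                              np.random.default_rng(0))
        x = rng.normal(size=(2, 256))
        assert block.forward(x).shape == (4, 256)


class TestNetwork:
    def test_output_length_and_empty_input(self, tiny_model, rng):
        x = rng.normal(size=512)
        assert tiny_model.forward(x).shape == (512,)
        with pytest.raises(ValidationError):
            tiny_model.forward(np.array([]))

    def test_identical_prefixes_give_identical_outputs(self, tiny_model, rng):
        x = rng.normal(size=64)
        x2 = x.copy()
        x2[40:] += 3.0
        y1 = tiny_model.forward(x)
        y2 = tiny_model.forward(x2)
        np.testing.assert_array_equal(y1[:40], y2[:40])

    def test_zero_weights_give_time_constant_output(self, tiny_config, rng):
        model = TCNAttention(tiny_config, seed=0)
        for p in model.params():
            p.value[...] = 0.0
        model.head.b.value[...] = 0.37
        y = model.forward(rng.normal(size=100))
        np.testing.assert_allclose(y, 0.37, atol=1e-12)

    def test_short_receptive_field_logs_warning(self, tiny_config, rng, caplog):
        model = TCNAttention(tiny_config, seed=0)
        with caplog.at_level(logging.WARNING, logger="capwave"):
            model.forward(rng.normal(size=256))
        assert any("receptive field" in m for m in caplog.messages)

    @pytest.mark.parametrize("attention", ["channel", "temporal", "none"])
    def test_gradients_match_finite_differences(self, attention):
        cfg = ModelConfig(k=2, num_levels=2, channels=3, dropout=0.0,
                          attention=attention, init_sd=0.3)
        model = TCNAttention(cfg, seed=3)
        x = np.random.default_rng(5).normal(size=12)
        y = np.random.default_rng(6).normal(size=12)
        y_hat = model.forward(x)
        model.zero_grad()
        model.backward(2.0 * (y_hat - y) / len(y))
        eps = 1e-6
        for p in model.params():
            it = np.nditer(p.value, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p.value[idx]
                p.value[idx] = orig + eps
                lp = mse_loss(y, model.forward(x))
                p.value[idx] = orig - eps
                lm = mse_loss(y, model.forward(x))
                p.value[idx] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(p.grad[idx], abs=5e-7), \
                    f"gradient mismatch at {p.name}{idx}"

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ModelConfig(k=0)
        with pytest.raises(ValidationError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValidationError):
            ModelConfig(attention="global")
        with pytest.raises(ValidationError):
            ModelConfig(num_levels=2, channels=(4,))
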