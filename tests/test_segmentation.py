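"""Encoder-decoder segmenter: block contracts, shape algebra, gradients, training."""

import numpy as np
import pytest

from mpalesion import nn
from mpalesion.nn import Tensor
from mpalesion.segmentation import (
    LedNetConfig,
    apn_decode,
    downsample_block,
    dice_coefficient,
    forward_logits,
    init_segmenter,
    load_segmenter,
    reduce_bands,
    save_segmenter,
    segment,
    ssnbt_block,
    train_segmenter,
)
from mpalesion.nn import shuffle_order


def tiny_config(**kw) -> LedNetConfig:
    base = dict(in_channels=2, base_channels=4, n_ssnbt_per_stage=1,
                n_downsamples=1, seed=0)
    base.update(kw)
    return LedNetConfig(**base)


class TestDownsampleBlock:
    def test_halves_spatial_and_concatenates_channels(self, rng):
        x = Tensor(rng.uniform(size=(1, 3, 16, 16)))
        w = Tensor(rng.normal(size=(5, 3, 3, 3)), requires_grad=True)
        b = Tensor(np.zeros(5), requires_grad=True)
        out = downsample_block(x, w, b)
        assert out.shape == (1, 5 + 3, 8, 8)

    def test_zero_input_zero_bias_gives_zero(self, rng):
        x = Tensor(np.zeros((1, 2, 8, 8)))
        w = Tensor(rng.normal(size=(2, 2, 3, 3)))
        out = downsample_block(x, w, Tensor(np.zeros(2)))
        assert np.all(out.data == 0)

    def test_pool_branch_equals_block_maxima(self):
        vals = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        x = Tensor(vals)
        w = Tensor(np.zeros((1, 1, 3, 3)))
        out = downsample_block(x, w, Tensor(np.zeros(1)))
        pooled = out.data[0, 1]  # channels: [conv, pool]
        expected = np.array([[5.0, 7.0], [13.0, 15.0]])
        assert np.array_equal(pooled, expected)

    def test_tiny_input_rejected(self, rng):
        x = Tensor(np.zeros((1, 1, 1, 4)))
        with pytest.raises(ValueError):
            downsample_block(x, Tensor(np.zeros((1, 1, 3, 3))), Tensor(np.zeros(1)))


class TestSsnbtBlock:
    def weights(self, half, rng, zero=False):
        out = {}
        for br in (1, 2):
            for tag, shape in (("w31", (half, half, 3, 1)), ("w13", (half, half, 1, 3))):
                data = np.zeros(shape) if zero else rng.normal(size=shape) * 0.1
                out[f"b{br}.{tag}"] = Tensor(data, requires_grad=True)
            out[f"b{br}.b31"] = Tensor(np.zeros(half), requires_grad=True)
            out[f"b{br}.b13"] = Tensor(np.zeros(half), requires_grad=True)
        return out

    def test_zero_weights_identity(self, rng):
        x = Tensor(np.abs(rng.uniform(size=(1, 8, 6, 6))))  # positive: final ReLU passthrough
        out = ssnbt_block(x, self.weights(4, rng, zero=True), dilation=2)
        assert np.allclose(out.data, x.data)

    def test_shape_preserved(self, rng):
        x = Tensor(rng.uniform(size=(2, 16, 8, 8)))
        out = ssnbt_block(x, self.weights(8, rng), dilation=2)
        assert out.shape == x.shape

    def test_odd_channels_rejected(self, rng):
        x = Tensor(rng.uniform(size=(1, 5, 6, 6)))
        with pytest.raises(ValueError):
            ssnbt_block(x, self.weights(2, rng))


def test_channel_shuffle_interleaves_two_groups():
    order = shuffle_order(16, groups=2)
    # channels 1..16 -> 1,9,2,10,... in 1-based terms
    assert np.array_equal(order + 1, [1, 9, 2, 10, 3, 11, 4, 12, 5, 13, 6, 14, 7, 15, 8, 16])
    x = Tensor(np.arange(16, dtype=float).reshape(1, 16, 1, 1))
    out = nn.channel_shuffle(x, groups=2)
    assert np.array_equal(out.data[0, :, 0, 0], order.astype(float))


class TestApnDecode:
    def make_weights(self, c_enc, rng, zero_pyramid=False):
        w = {}
        for i, k in enumerate((3, 5, 7)):
            cin = c_enc if i == 0 else 1
            data = np.zeros((1, cin, k, k)) if zero_pyramid else rng.normal(size=(1, cin, k, k)) * 0.1
            w[f"p{i}.w"] = Tensor(data, requires_grad=True)
            w[f"p{i}.b"] = Tensor(np.zeros(1), requires_grad=True)
        w["proj.w"] = Tensor(rng.normal(size=(1, c_enc, 1, 1)), requires_grad=True)
        w["proj.b"] = Tensor(np.zeros(1), requires_grad=True)
        w["gap.w"] = Tensor(rng.normal(size=(1, c_enc, 1, 1)), requires_grad=True)
        w["gap.b"] = Tensor(np.zeros(1), requires_grad=True)
        return w

    def test_output_at_requested_resolution(self, rng):
        enc = Tensor(rng.uniform(size=(1, 4, 16, 16)))
        out = apn_decode(enc, self.make_weights(4, rng), (64, 64))
        assert out.shape == (1, 1, 64, 64)

    def test_zero_pyramid_reduces_to_pooling_branch(self, rng):
        enc = Tensor(rng.uniform(size=(2, 4, 8, 8)))
        w = self.make_weights(4, rng, zero_pyramid=True)
        out = apn_decode(enc, w, (8, 8))
        gap = enc.data.mean(axis=(2, 3))  # (2, 4)
        expected = (gap * w["gap.w"].data[0, :, 0, 0]).sum(axis=1)
        for i in range(2):
            assert np.allclose(out.data[i, 0], expected[i])

    def test_input_smaller_than_pyramid_rejected(self, rng):
        enc = Tensor(rng.uniform(size=(1, 4, 4, 4)))
        with pytest.raises(ValueError):
            apn_decode(enc, self.make_weights(4, rng), (16, 16))


class TestForwardAndSegment:
    @pytest.mark.parametrize("size", [32, 64])
    def test_output_matches_input_resolution(self, rng, size):
        cfg = tiny_config()
        model = init_segmenter(cfg)
        logits = forward_logits(model, rng.uniform(size=(1, 2, size, size)))
        assert logits.shape == (1, 1, size, size)

    def test_probabilities_bounded_and_finite(self, rng, small_dataset):
        cfg = LedNetConfig(in_channels=8, base_channels=16, seed=0)
        model = init_segmenter(cfg)
        probs = segment(small_dataset[0], model)
        assert probs.shape == small_dataset[0].mask.shape
        assert np.all(np.isfinite(probs)) and probs.min() >= 0 and probs.max() <= 1

    def test_segment_deterministic(self, small_dataset):
        cfg = LedNetConfig(in_channels=8, base_channels=16, seed=4)
        a = segment(small_dataset[0], init_segmenter(cfg))
        b = segment(small_dataset[0], init_segmenter(cfg))
        assert np.array_equal(a, b)

    def test_channel_mismatch_rejected(self, rng):
        model = init_segmenter(tiny_config(in_channels=4, base_channels=8))
        with pytest.raises(ValueError):
            segment(rng.uniform(size=(16, 16, 2)), model)  # fewer wavelengths than bands


class TestGradients:
    def test_decoder_gradients_match_central_differences(self, rng):
        """Probe set: decoder parameters, which sit behind smooth ops only."""
        cfg = tiny_config()
        model = init_segmenter(cfg)
        x = rng.uniform(size=(1, 2, 16, 16))
        t = (rng.uniform(size=(1, 1, 16, 16)) > 0.7).astype(float)

        def loss_val():
            return float(nn.bce_with_logits(forward_logits(model, x), t).data)

        model.zero_grad()
        nn.bce_with_logits(forward_logits(model, x), t).backward()
        eps = 1e-6
        for name in ("apn.proj.w", "apn.gap.w", "apn.p1.w"):
            p = model.params[name]
            flat, g = p.data.ravel(), p.grad.ravel()
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_val()
                flat[idx] = orig - eps
                lm = loss_val()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) / max(1e-8, abs(num) + abs(g[idx])) < 1e-4


class TestTraining:
    def test_loss_decreases(self, small_dataset):
        cfg = LedNetConfig(in_channels=8, base_channels=16, seed=0)
        model = train_segmenter(small_dataset[:4], cfg, n_steps=30, lr=0.5)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_zero_learning_rate_leaves_parameters(self, small_dataset):
        cfg = tiny_config(in_channels=8, base_channels=12, seed=7)
        trained = train_segmenter(small_dataset[:2], cfg, n_steps=3, lr=0.0)
        ref = init_segmenter(cfg)
        for k in ref.params:
            assert np.array_equal(trained.params[k].data, ref.params[k].data)

    def test_final_loss_deterministic(self, small_dataset):
        cfg = tiny_config(in_channels=8, base_channels=12, seed=2)
        a = train_segmenter(small_dataset[:2], cfg, n_steps=5, lr=0.3)
        b = train_segmenter(small_dataset[:2], cfg, n_steps=5, lr=0.3)
        assert a.loss_history == b.loss_history

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter([], tiny_config())


def test_reduce_bands_uniform_averaging():
    stack = np.stack([np.full((4, 4), float(k)) for k in range(8)], axis=2)
    out = reduce_bands(stack, 4)
    assert out.shape == (4, 4, 4)
    assert np.allclose(out[0, 0], [0.5, 2.5, 4.5, 6.5])


def test_dice_coefficient_edge_cases():
    a = np.zeros((4, 4), bool)
    b = np.zeros((4, 4), bool)
    assert dice_coefficient(a, b) == 1.0
    b[0, 0] = True
    assert dice_coefficient(a, b) == 0.0
    assert dice_coefficient(b, b) == 1.0


def test_segmenter_json_roundtrip(tmp_path, small_dataset):
    cfg = tiny_config(in_channels=8, base_channels=12, seed=1)
    model = train_segmenter(small_dataset[:2], cfg, n_steps=2, lr=0.1)
    save_segmenter(model, tmp_path / "seg.json")
    loaded = load_segmenter(tmp_path / "seg.json")
    a = segment(small_dataset[0], model)
    b = segment(small_dataset[0], loaded)
    assert np.allclose(a, b)
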