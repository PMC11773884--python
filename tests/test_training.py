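"""Initialization, loss, gradient accumulation, and the training loop."""

import dataclasses
import math

import numpy as np
import pytest

from finpose.augment import AugmentConfig, SplitStats, split_dataset, standardize
from finpose.codec import CodecConfig, encode_targets
from finpose.nn.layers import Conv2d, Normalization
from finpose.nn.model import NetworkConfig, build_network
from finpose.training import (
    AdamW,
    TrainConfig,
    ablation_experiment,
    evaluate,
    init_weights,
    mse_loss,
    mse_loss_grad,
    train,
)


class TestInitWeights:
    def test_final_conv_and_all_biases_are_zero(self, tiny_cfg):
        net = build_network(tiny_cfg)
        init_weights(net, 0)
        finals = [l for l in net.layers() if getattr(l, "network_final", False)]
        assert len(finals) == 1
        assert np.all(finals[0].weight.value == 0.0)
        for layer in net.layers():
            if isinstance(layer, Conv2d) and layer.bias is not None:
                assert np.all(layer.bias.value == 0.0)

    def test_deterministic_given_seed(self, tiny_cfg):
        a = build_network(tiny_cfg)
        b = build_network(tiny_cfg)
        init_weights(a, 5)
        init_weights(b, 5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_block_projection_sd_scales_with_inverse_sqrt_n(self):
        # Xavier-uniform SD = gain * sqrt(2 / (fan_in + fan_out)); the block's
        # last conv uses gain 1/sqrt(N).  Check the empirical SD at N=10.
        cfg = NetworkConfig(H=64, W=64, M=32, O=1, N=10)
        net = build_network(cfg)
        init_weights(net, 0)
        projections = [
            l for l in net.layers() if getattr(l, "residual_last", False)
        ]
        assert len(projections) == 10
        values = np.concatenate([p.weight.value.ravel() for p in projections])
        fan_in, fan_out = 64, 32
        expected_sd = (1 / math.sqrt(10)) * math.sqrt(2.0 / (fan_in + fan_out))
        assert abs(values.std() - expected_sd) / expected_sd < 0.10


class TestLoss:
    def test_zero_when_equal(self):
        x = np.random.default_rng(0).standard_normal((2, 3, 4, 4))
        assert mse_loss(x, x.copy()) == 0.0

    def test_constant_offset_squares(self):
        x = np.zeros((2, 1, 8, 8))
        assert mse_loss(x + 0.3, x) == pytest.approx(0.09)

    def test_initial_loss_equals_mean_squared_target(self, tiny_cfg, tiny_dataset):
        """Zero-init output forces loss == mean(target^2), computed
        independently from the codec."""
        net = build_network(tiny_cfg)
        init_weights(net, 1)
        cfg = CodecConfig(sigma=2.0)
        frames = tiny_dataset.frames[:8]
        stats = SplitStats(mean=0.5, sd=0.25)
        x = np.stack([standardize(f.image, stats) for f in frames])[:, None].astype(np.float32)
        target = np.stack(
            [encode_targets(f.keypoints, (32, 32), cfg).values for f in frames]
        ).astype(np.float32)
        pred = net.forward(x)
        assert np.all(pred == 0.0)
        independent = float(np.mean(np.square(target, dtype=np.float64)))
        assert mse_loss(pred, target) == pytest.approx(independent, abs=1e-6)

    def test_grad_matches_definition(self):
        rng = np.random.default_rng(1)
        pred = rng.standard_normal((2, 1, 4, 4))
        target = rng.standard_normal((2, 1, 4, 4))
        np.testing.assert_allclose(
            mse_loss_grad(pred, target), 2 * (pred - target) / pred.size
        )


def batch_gradients(net, x, target):
    net.zero_grad()
    pred = net.forward(x, training=True)
    net.backward(mse_loss_grad(pred, target).astype(np.float32))
    return [p.grad.copy() for p in net.parameters()]


def accumulated_gradients(net, x, target):
    net.zero_grad()
    n = x.shape[0]
    for i in range(n):
        pred = net.forward(x[i : i + 1], training=True)
        net.backward(mse_loss_grad(pred, target[i : i + 1]).astype(np.float32) / n)
    return [p.grad.copy() for p in net.parameters()]


def rel_diff(a, b):
    num = math.sqrt(sum(float(np.sum((x - y) ** 2)) for x, y in zip(a, b)))
    den = math.sqrt(sum(float(np.sum(x**2)) for x in a))
    return num / den


class TestGradientAccumulation:
    @pytest.mark.parametrize("norm", ["instance", "layer", "group"])
    def test_microbatch_accumulation_matches_full_batch(self, norm):
        cfg = NetworkConfig(H=32, W=32, M=8, O=1, N=2, norm=norm, drop_prob=0.0)
        net = build_network(cfg)
        init_weights(net, 0)
        # Break the zero-output degeneracy so gradients reach every layer.
        for layer in net.layers():
            if getattr(layer, "network_final", False):
                layer.weight.value[...] = 0.01
        rng = np.random.default_rng(0)
        x = rng.standard_normal((16, 1, 32, 32)).astype(np.float32)
        target = rng.standard_normal((16, 1, 16, 16)).astype(np.float32) * 0.1
        full = batch_gradients(net, x, target)
        acc = accumulated_gradients(net, x, target)
        assert rel_diff(full, acc) < 1e-5

    def test_batch_norm_breaks_the_equivalence(self):
        cfg = NetworkConfig(H=32, W=32, M=8, O=1, N=2, norm="batch", drop_prob=0.0)
        net = build_network(cfg)
        init_weights(net, 0)
        for layer in net.layers():
            if getattr(layer, "network_final", False):
                layer.weight.value[...] = 0.01
        rng = np.random.default_rng(0)
        x = rng.standard_normal((16, 1, 32, 32)).astype(np.float32)
        target = rng.standard_normal((16, 1, 16, 16)).astype(np.float32) * 0.1
        full = batch_gradients(net, x, target)
        # reset running stats so the micro-batch pass starts identically
        init_weights(net, 0)
        for layer in net.layers():
            if getattr(layer, "network_final", False):
                layer.weight.value[...] = 0.01
        acc = accumulated_gradients(net, x, target)
        assert rel_diff(full, acc) > 1e-3


class TestAdamW:
    def test_weight_decay_touches_only_conv_weights(self, tiny_cfg):
        net = build_network(tiny_cfg)
        init_weights(net, 2)
        for layer in net.layers():
            if isinstance(layer, Normalization):
                layer.gamma.value[...] = 2.0  # make decay visible if applied
        params = net.parameters()
        before = [p.value.copy() for p in params]
        opt = AdamW(params, TrainConfig(weight_decay=0.1, learning_rate=1e-3))
        for p in params:
            p.grad[...] = 0.0
        opt.step()
        for p, b in zip(params, before):
            if p.decay and np.any(b != 0):
                assert np.max(np.abs(p.value - b)) > 0
            else:
                np.testing.assert_array_equal(p.value, b)


class TestTrainLoop:
    def test_short_run_reduces_validation_loss(self, tiny_cfg, tiny_dataset):
        net = build_network(tiny_cfg)
        init_weights(net, 0)
        train_ds, val_ds = split_dataset(tiny_dataset, 0.75, seed=0)
        tcfg = TrainConfig(n_updates=200, seed=0, eval_interval=100, learning_rate=2e-3)
        history = train(net, train_ds, val_ds, tcfg)
        assert history.val_loss[-1] < history.val_loss[0]
        assert history.updates == [100, 200]

    def test_bitwise_reproducible_given_seed(self, tiny_cfg, tiny_dataset):
        train_ds, val_ds = split_dataset(tiny_dataset, 0.75, seed=0)
        tcfg = TrainConfig(n_updates=20, seed=3, eval_interval=20)
        results = []
        for _ in range(2):
            net = build_network(tiny_cfg)
            init_weights(net, 3)
            history = train(net, train_ds, val_ds, tcfg)
            results.append((history.val_loss[-1], [p.value.copy() for p in net.parameters()]))
        assert results[0][0] == results[1][0]
        for a, b in zip(results[0][1], results[1][1]):
            np.testing.assert_array_equal(a, b)

    def test_effective_batch_must_divide(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=16, effective_batch=24)


class TestAblation:
    def test_table_shape_and_fraction_one_reference(self, tiny_cfg, tiny_dataset):
        tcfg = TrainConfig(n_updates=10, seed=0, eval_interval=10)
        table = ablation_experiment(
            tiny_dataset, [0.5, 1.0], n_seeds=2, tcfg=tcfg,
            acfg=AugmentConfig.identity(), net_cfg=tiny_cfg,
        )
        assert len(table) == 4
        full = table[table["fraction"] == 1.0]
        assert (full["relative_accuracy"] == 1.0).all()

    def test_zero_training_images_rejected(self, tiny_cfg, tiny_dataset):
        with pytest.raises(ValueError):
            ablation_experiment(
                tiny_dataset, [0.001], n_seeds=1,
                tcfg=TrainConfig(n_updates=1, eval_interval=1),
                net_cfg=tiny_cfg,
            )
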