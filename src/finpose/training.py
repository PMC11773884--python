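"""Training loop: MSE heatmap regression with AdamW and gradient accumulation.

The recipe: batch size 16, AdamW (beta1 0.9, beta2 0.95, eps 1e-6), learning
rate 5e-4 for single-well escape-response networks or 1e-4 for multiwell
visuomotor networks, decoupled weight decay 1e-5 on convolution weights only,
6000 parameter updates with on-the-fly augmentation of the training split.
Convolution weights use Xavier initialization -- gain sqrt(2) where a
nonlinearity (directly or after a normalization) follows, 1 otherwise, the
last convolution of each residual block additionally scaled by 1/sqrt(N) --
and the final convolution layer starts at zero, so the freshly initialized
network outputs identically zero heatmaps.  All biases start at zero.

Batches are drawn uniformly with replacement per update.  An effective batch
larger than the micro-batch size is reached by accumulating gradients; in the
absence of batch normalization this changes nothing but memory use.  Runs are
bit-reproducible on a single thread for a fixed (seed, config).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import AugmentConfig, SplitStats, augment_pair, compute_split_stats, split_dataset, standardize
from .codec import CodecConfig, Keypoints, count_correct, decode_heatmaps, encode_targets, HeatmapStack
from .nn.layers import Conv2d, ConvTranspose2d, Normalization, Param
from .nn.model import Network
from .synthetic import LabeledFrame, PoseDataset

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "AdamW",
    "init_weights",
    "mse_loss",
    "mse_loss_grad",
    "train",
    "evaluate",
    "ablation_experiment",
]


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.95
    adam_eps: float = 1e-6
    weight_decay: float = 1e-5
    batch_size: int = 16
    effective_batch: int = 16
    n_updates: int = 6000
    seed: int = 0
    eval_interval: int = 100

    def __post_init__(self) -> None:
        if self.effective_batch % self.batch_size:
            raise ValueError("effective_batch must be a multiple of batch_size")
        if self.n_updates < 1 or self.batch_size < 1:
            raise ValueError("n_updates and batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Loss trajectory of one run, recorded every ``eval_interval`` updates."""

    updates: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "update": self.updates,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "wall_time_s": self.wall_time,
            }
        )


def init_weights(net: Network, seed: int = 0) -> None:
    """Apply the documented initialization scheme, deterministically.

    Xavier-uniform convolution weights with per-layer gains annotated at build
    time (sqrt(2) before a nonlinearity, 1 otherwise, 1/sqrt(N) on each
    block's last convolution); the network's final convolution and all biases
    are exactly zero, so the initial output is identically zero.
    Normalization affine parameters reset to gamma 1, beta 0.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    for layer in net.layers():
        if isinstance(layer, (Conv2d, ConvTranspose2d)):
            w = layer.weight.value
            if getattr(layer, "init_zero", False) or getattr(layer, "network_final", False):
                w[...] = 0.0
            else:
                limit = layer.init_gain * math.sqrt(6.0 / (layer.fan_in + layer.fan_out))
                w[...] = rng.uniform(-limit, limit, size=w.shape).astype(w.dtype)
            if layer.bias is not None:
                layer.bias.value[...] = 0.0
        elif isinstance(layer, Normalization):
            layer.gamma.value[...] = 1.0
            layer.beta.value[...] = 0.0
            if layer.kind == "batch":
                layer.running_mean[...] = 0.0
                layer.running_var[...] = 1.0


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over all elements of the squared difference."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(diff * diff))


def mse_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d(mean squared error)/d(pred)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return (2.0 / pred.size) * (pred - target)


class AdamW:
    """AdamW with decoupled weight decay restricted to decay-flagged params."""

    def __init__(self, params: list[Param], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float32) for p in params]

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= c.beta1
            m += (1.0 - c.beta1) * g
            v *= c.beta2
            v += (1.0 - c.beta2) * g * g
            if p.decay and c.weight_decay:
                p.value -= (c.learning_rate * c.weight_decay) * p.value
            p.value -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.adam_eps)


def _standardized_batch(frames: list[LabeledFrame], stats: SplitStats) -> np.ndarray:
    return np.stack([standardize(f.image, stats) for f in frames])[:, None, :, :]


def _targets(
    frames: list[LabeledFrame],
    heatmap_shape: tuple[int, int],
    codec_cfg: CodecConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    return np.stack(
        [encode_targets(f.keypoints, heatmap_shape, codec_cfg, rng).values for f in frames]
    )


def evaluate(
    net: Network,
    frames: list[LabeledFrame],
    stats: SplitStats,
    codec_cfg: CodecConfig | None = None,
    radius: float | None = None,
    batch_size: int = 16,
) -> dict:
    """Validation loss and keypoint accuracy, without augmentation or dropout."""
    codec_cfg = codec_cfg or CodecConfig()
    radius = radius if radius is not None else codec_cfg.correctness_radius
    cfg = net.cfg
    hm_shape = (cfg.H // 2, cfg.W // 2)
    losses = []
    n_correct = 0
    total_kp = 0
    for i in range(0, len(frames), batch_size):
        chunk = frames[i : i + batch_size]
        x = _standardized_batch(chunk, stats).astype(np.float32)
        target = _targets(chunk, hm_shape, codec_cfg, rng=None).astype(np.float32)
        pred = net.forward(x, training=False)
        losses.append(mse_loss(pred, target) * len(chunk))
        for j, f in enumerate(chunk):
            decoded = decode_heatmaps(HeatmapStack(pred[j]))
            n_correct += count_correct([decoded], [f.keypoints], radius)
            total_kp += f.keypoints.n_keypoints
    return {
        "loss": sum(losses) / len(frames),
        "pck": n_correct / total_kp,
        "n_correct": n_correct,
        "n_keypoints": total_kp,
    }


def train(
    net: Network,
    train_split: PoseDataset | list[LabeledFrame],
    val_split: PoseDataset | list[LabeledFrame],
    tcfg: TrainConfig | None = None,
    acfg: AugmentConfig | None = None,
    codec_cfg: CodecConfig | None = None,
    stats: SplitStats | None = None,
) -> TrainHistory:
    """Run ``n_updates`` AdamW steps of heatmap MSE regression.

    Training frames are sampled uniformly with replacement per update and
    augmented on the fly; validation frames are only standardized and are
    evaluated (without dropout) every ``eval_interval`` updates.
    Standardization statistics come from the training split.  Raises on a
    non-finite loss.
    """
    tcfg = tcfg or TrainConfig()
    acfg = acfg or AugmentConfig()
    codec_cfg = codec_cfg or CodecConfig()
    train_frames = train_split.frames if isinstance(train_split, PoseDataset) else train_split
    val_frames = val_split.frames if isinstance(val_split, PoseDataset) else val_split
    if not train_frames or not val_frames:
        raise ValueError("train and validation splits must be nonempty")
    if stats is None:
        pooled = np.stack([f.image for f in train_frames])
        sd = float(pooled.std())
        if sd == 0:
            raise ValueError("training images are constant; cannot standardize")
        stats = SplitStats(mean=float(pooled.mean()), sd=sd)

    rng_batch = np.random.Generator(np.random.PCG64(np.random.SeedSequence(tcfg.seed, spawn_key=(0,))))
    rng_aug = np.random.Generator(np.random.PCG64(np.random.SeedSequence(tcfg.seed, spawn_key=(1,))))
    rng_wiggle = np.random.Generator(np.random.PCG64(np.random.SeedSequence(tcfg.seed, spawn_key=(2,))))
    rng_drop = np.random.Generator(np.random.PCG64(np.random.SeedSequence(tcfg.seed, spawn_key=(3,))))

    cfg = net.cfg
    hm_shape = (cfg.H // 2, cfg.W // 2)
    n_micro = tcfg.effective_batch // tcfg.batch_size
    opt = AdamW(net.parameters(), tcfg)
    history = TrainHistory()
    t0 = time.perf_counter()
    running: list[float] = []

    for update in range(1, tcfg.n_updates + 1):
        net.zero_grad()
        update_loss = 0.0
        for _ in range(n_micro):
            idx = rng_batch.integers(0, len(train_frames), size=tcfg.batch_size)
            batch = []
            for i in idx:
                frame = train_frames[int(i)]
                batch.append(augment_pair(frame, acfg, stats, rng_aug))
            x = np.stack([f.image for f in batch])[:, None].astype(np.float32)
            target = _targets(
                batch, hm_shape, codec_cfg, rng_wiggle if acfg.enabled else None
            ).astype(np.float32)
            pred = net.forward(x, training=True, rng=rng_drop)
            loss = mse_loss(pred, target)
            if not math.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at update {update}")
            update_loss += loss / n_micro
            net.backward(mse_loss_grad(pred, target).astype(np.float32) / n_micro)
        opt.step()
        running.append(update_loss)

        if update % tcfg.eval_interval == 0 or update == tcfg.n_updates:
            val = evaluate(net, val_frames, stats, codec_cfg, batch_size=tcfg.batch_size)
            history.updates.append(update)
            history.train_loss.append(float(np.mean(running)))
            history.val_loss.append(val["loss"])
            history.wall_time.append(time.perf_counter() - t0)
            running = []
    return history


def ablation_experiment(
    dataset: PoseDataset,
    fractions: list[float],
    n_seeds: int,
    tcfg: TrainConfig | None = None,
    acfg: AugmentConfig | None = None,
    codec_cfg: CodecConfig | None = None,
    net_cfg=None,
) -> pd.DataFrame:
    """Train-data ablation: shrink the training split, keep validation fixed.

    For each seed the dataset is partitioned once; each requested fraction of
    the training split is then used to train a fresh network for the same
    number of parameter updates, and scored on the constant validation split.
    Relative accuracy divides each run's correctly predicted keypoint count by
    that of the same seed's full-data run.  Returns one row per
    (fraction, seed).
    """
    from .nn.model import NetworkConfig, build_network

    tcfg = tcfg or TrainConfig()
    acfg = acfg or AugmentConfig()
    codec_cfg = codec_cfg or CodecConfig()
    if net_cfg is None:
        raise ValueError("net_cfg (a NetworkConfig) is required")
    fracs = sorted(set(fractions) | {1.0}, reverse=True)
    if any(not 0.0 < f <= 1.0 for f in fracs):
        raise ValueError("fractions must lie in (0, 1]")

    rows = []
    for seed in range(n_seeds):
        train_ds, val_ds = split_dataset(dataset, 0.75, seed=seed)
        stats = compute_split_stats(train_ds)
        full_correct: int | None = None
        for frac in fracs:
            n_keep = int(round(frac * len(train_ds)))
            if n_keep == 0:
                raise ValueError(f"fraction {frac} leaves zero training images")
            ablated = train_ds.frames[:n_keep]
            net = build_network(net_cfg)
            init_weights(net, seed=seed)
            run_cfg = replace(tcfg, seed=seed)
            history = train(net, ablated, val_ds.frames, run_cfg, acfg, codec_cfg, stats=stats)
            score = evaluate(net, val_ds.frames, stats, codec_cfg)
            if frac == 1.0:
                full_correct = score["n_correct"]
            rel = (
                score["n_correct"] / full_correct
                if full_correct and full_correct > 0
                else float("nan")
            )
            rows.append(
                {
                    "fraction": frac,
                    "seed": seed,
                    "n_train": n_keep,
                    "final_val_loss": history.val_loss[-1],
                    "pck": score["pck"],
                    "relative_accuracy": rel if frac != 1.0 else 1.0,
                }
            )
    keep = set(fractions) | {1.0}
    out = pd.DataFrame(rows)
    return out[out["fraction"].isin(keep)].reset_index(drop=True)
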