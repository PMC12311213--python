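"""Deep-feature extraction behind a pluggable backbone contract.

The reference backbone is a 50-layer bottleneck residual network (the
conv1 + [3,4,6,3] bottleneck-stage architecture) with the classification
head removed: the globally average-pooled activation of the last stage is
the 2048-dimensional feature vector. It is implemented here forward-only in
NumPy with He-initialised random weights; normalisation layers use the
input's own per-channel spatial statistics, which keeps activations on a
sane scale at any depth without trained running averages. Pretrained
ImageNet weights can be plugged in through the same contract but are never
required — randomly initialised convolutional features are already a valid
(if weaker) feature extractor, and every dimensionality contract holds
regardless of weights.

A small trainable-head ``fine_tune`` is provided: it fits a temporary
binary softmax head on the frozen backbone features (Adam, cross-entropy)
and discards it, returning the backbone plus the training history.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._utils import as_binary_labels, check_finite


@dataclass
class BackboneContract:
    """A feature extractor: maps a batch of square grayscale images
    (n, size, size) to an (n, feature_dim) matrix, deterministically."""

    name: str
    feature_dim: int
    apply: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be positive")


@dataclass(frozen=True)
class FineTuneConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("rates and sizes must be positive (epochs >= 0)")


def _as_batch(images) -> np.ndarray:
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError(f"expected (n, size, size) batch, got {arr.shape}")
    return arr


def extract_features(images, backbone: BackboneContract) -> np.ndarray:
    """Run the backbone on a batch; rows follow input order."""
    batch = _as_batch(images)
    feats = np.asarray(backbone.apply(batch), dtype=float)
    if feats.shape != (batch.shape[0], backbone.feature_dim):
        raise ValueError(
            f"backbone {backbone.name!r} returned {feats.shape}, "
            f"expected ({batch.shape[0]}, {backbone.feature_dim})"
        )
    return check_finite(feats, "features")


# ---------------------------------------------------------------------------
# NumPy conv primitives (forward only)
# ---------------------------------------------------------------------------

def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: (c_in, h, w); w: (c_out, c_in, k, k) -> (c_out, h', w'). im2col."""
    c_in, h, wd = x.shape
    c_out, _, k, _ = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    h_p, w_p = x.shape[1], x.shape[2]
    oh = (h_p - k) // stride + 1
    ow = (w_p - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(c_in, oh, ow, k, k),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2]),
        writeable=False,
    )
    cols = windows.transpose(1, 2, 0, 3, 4).reshape(oh * ow, c_in * k * k)
    out = cols @ w.reshape(c_out, -1).T
    return np.ascontiguousarray(out.T.reshape(c_out, oh, ow))


def _instance_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def _maxpool(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    h_p, w_p = x.shape[1], x.shape[2]
    oh = (h_p - k) // stride + 1
    ow = (w_p - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(c, oh, ow, k, k),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2]),
        writeable=False,
    )
    return windows.max(axis=(3, 4))


class ResidualBackbone:
    """50-layer bottleneck residual feature extractor (head removed).

    Stages of [3, 4, 6, 3] bottleneck blocks with base widths 64/128/256/512
    and 4x expansion; conv1 is 7x7 stride 2, followed by 3x3 stride-2 max
    pooling; features are the 2048-wide global average pool of the last
    stage. Weights are He-normal random draws from ``seed`` (or supplied
    externally); single-channel input is replicated to three channels.
    """

    STAGES = ((3, 64), (4, 128), (6, 256), (3, 512))
    EXPANSION = 4

    def __init__(self, seed: int = 0, input_size: int = 224):
        self.seed = seed
        self.input_size = input_size
        self.feature_dim = self.STAGES[-1][1] * self.EXPANSION  # 2048
        self._weights = self._init_weights(np.random.default_rng(seed))

    def _he(self, rng, c_out, c_in, k) -> np.ndarray:
        std = np.sqrt(2.0 / (c_in * k * k))
        return rng.standard_normal((c_out, c_in, k, k)) * std

    def _init_weights(self, rng) -> dict:
        w: dict[str, np.ndarray] = {"conv1": self._he(rng, 64, 3, 7)}
        c_in = 64
        for si, (blocks, width) in enumerate(self.STAGES):
            c_out = width * self.EXPANSION
            for bi in range(blocks):
                p = f"s{si}b{bi}"
                w[f"{p}c1"] = self._he(rng, width, c_in, 1)
                w[f"{p}c2"] = self._he(rng, width, width, 3)
                w[f"{p}c3"] = self._he(rng, c_out, width, 1)
                if bi == 0:
                    w[f"{p}proj"] = self._he(rng, c_out, c_in, 1)
                c_in = c_out
        return w

    def _forward_one(self, img: np.ndarray) -> np.ndarray:
        x = np.repeat(img[None], 3, axis=0)  # gray -> 3 channels
        w = self._weights
        x = np.maximum(_instance_norm(_conv2d(x, w["conv1"], stride=2, pad=3)), 0.0)
        x = _maxpool(x, k=3, stride=2, pad=1)
        for si, (blocks, width) in enumerate(self.STAGES):
            for bi in range(blocks):
                p = f"s{si}b{bi}"
                stride = 2 if (bi == 0 and si > 0) else 1
                identity = x
                out = np.maximum(_instance_norm(_conv2d(x, w[f"{p}c1"], 1, 0)), 0.0)
                out = np.maximum(_instance_norm(_conv2d(out, w[f"{p}c2"], stride, 1)), 0.0)
                out = _instance_norm(_conv2d(out, w[f"{p}c3"], 1, 0))
                if bi == 0:
                    identity = _instance_norm(_conv2d(x, w[f"{p}proj"], stride, 0))
                x = np.maximum(out + identity, 0.0)
        return x.mean(axis=(1, 2))  # global average pool -> (2048,)

    def apply(self, batch: np.ndarray) -> np.ndarray:
        return np.stack([self._forward_one(img) for img in batch])

    def contract(self) -> BackboneContract:
        return BackboneContract(
            name=f"residual50-random-seed{self.seed}", feature_dim=self.feature_dim, apply=self.apply
        )


class TinyCNNBackbone:
    """Two-conv-layer random-feature CNN for fast tests and toy images.

    No normalisation layers, so absolute intensity structure (e.g. the dark
    area of a hypoechoic lesion) survives into the features; each channel
    contributes its spatial mean and max, giving ``feature_dim`` features
    from ``feature_dim / 2`` channels (``feature_dim`` must be even).
    """

    def __init__(self, feature_dim: int = 16, seed: int = 0):
        if feature_dim % 2:
            raise ValueError("feature_dim must be even (mean+max pooling per channel)")
        rng = np.random.default_rng(seed)
        self.feature_dim = feature_dim
        self.seed = seed
        c2 = feature_dim // 2
        self.w1 = rng.standard_normal((8, 3, 5, 5)) * np.sqrt(2.0 / 75)
        self.w2 = rng.standard_normal((c2, 8, 3, 3)) * np.sqrt(2.0 / 72)

    def _forward_one(self, img: np.ndarray) -> np.ndarray:
        x = np.repeat(img[None], 3, axis=0)
        x = np.maximum(_conv2d(x, self.w1, stride=2, pad=2), 0.0)
        x = np.maximum(_conv2d(x, self.w2, stride=2, pad=1), 0.0)
        return np.concatenate([x.mean(axis=(1, 2)), x.max(axis=(1, 2))])

    def apply(self, batch: np.ndarray) -> np.ndarray:
        return np.stack([self._forward_one(img) for img in batch])

    def contract(self) -> BackboneContract:
        return BackboneContract(
            name=f"tinycnn-{self.feature_dim}-seed{self.seed}",
            feature_dim=self.feature_dim,
            apply=self.apply,
        )


# ---------------------------------------------------------------------------
# fine-tuning of a temporary binary head
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def fine_tune(
    backbone: BackboneContract,
    images,
    labels,
    cfg: FineTuneConfig = FineTuneConfig(),
) -> tuple[BackboneContract, dict]:
    """Train a temporary binary softmax head on the backbone's features with
    minibatch Adam + cross-entropy, then drop the head.

    Returns the backbone (features unchanged — the head never feeds back into
    extraction) and a history dict with per-epoch loss and the final training
    accuracy of the temporary head. With ``epochs=0`` nothing is trained.
    """
    y = as_binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("fine_tune requires both classes present")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")

    feats = extract_features(images, backbone)
    # z-score the frozen features so the head optimises on a sane scale
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - mu) / sd
    n, d = feats.shape
    rng = np.random.default_rng(cfg.seed)
    W = np.zeros((d, 2))
    b = np.zeros(2)
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    onehot = np.eye(2)[y]

    losses: list[float] = []
    t = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            X = feats[idx]
            Z = _softmax(X @ W + b)
            epoch_loss += -np.sum(np.log(Z[np.arange(len(idx)), y[idx]] + 1e-12))
            G = (Z - onehot[idx]) / len(idx)
            gW = X.T @ G
            gb = G.sum(axis=0)
            t += 1
            for g, m, v, param in ((gW, mW, vW, W), (gb, mb, vb, b)):
                m *= beta1; m += (1 - beta1) * g
                v *= beta2; v += (1 - beta2) * g * g
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                param -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        losses.append(epoch_loss / n)

    pred = np.argmax(feats @ W + b, axis=1)
    history = {
        "loss": losses,
        "head_train_accuracy": float(np.mean(pred == y)),
        "epochs_run": cfg.epochs,
    }
    return backbone, history
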