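"""Channel-spatial attention convolutional network for multichannel sEMG.

The classifier stacks three attention-convolution cells (conv → channel
attention → spatial attention → batch-norm → ReLU → max-pool), a fully
connected layer and a softmax. Channel attention gates whole feature maps
through a squeeze-excite bottleneck fed by the sum of global average and
global max pooling; spatial attention gates pixels through a k×k convolution
of the channel-pooled maps. Both gates are sigmoids, so attention can only
shrink a feature, never amplify it — unimportant responses are driven toward
zero, a soft-threshold effect.

Ablation variants replace the removed attention block with a conventional
depthwise 3×3 convolution, keeping the parameter budget essentially
unchanged so architecture comparisons are not confounded by capacity:

- ``csac``: both attentions (the full model);
- ``sac``: spatial attention only;
- ``cac``: channel attention only;
- ``cnn``: no attention.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "ChannelAttentionParams", "SpatialAttentionParams", "NetworkConfig",
    "CSACNet", "channel_attention", "spatial_attention", "cross_entropy",
]

VARIANTS = ("csac", "sac", "cac", "cnn")


@dataclass
class ChannelAttentionParams:
    """Squeeze-excite bottleneck: C -> C/r -> C."""

    w1: Tensor  # (C/r, C)
    b1: Tensor
    w2: Tensor  # (C, C/r)
    b2: Tensor

    @classmethod
    def init(cls, rng, channels, reduction):
        if channels % reduction:
            raise ValueError(f"reduction {reduction} must divide channel count {channels}")
        hidden = channels // reduction
        return cls(
            w1=nn.he_normal(rng, (hidden, channels), channels),
            b1=nn.zeros_param((hidden,)),
            w2=nn.he_normal(rng, (channels, hidden), hidden),
            b2=nn.zeros_param((channels,)),
        )

    def tensors(self):
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}


@dataclass
class SpatialAttentionParams:
    """Scalar gains on the two channel-pooled maps, then a k×k conv to one map."""

    w1: Tensor  # (1,) gain on channel-GAP map
    b1: Tensor
    w2: Tensor  # (1,) gain on channel-GMP map
    b2: Tensor
    w3: Tensor  # (1, 1, k, k)
    b3: Tensor

    @classmethod
    def init(cls, rng, kernel):
        return cls(
            w1=Tensor(np.array([1.0]), requires_grad=True),
            b1=nn.zeros_param((1,)),
            w2=Tensor(np.array([1.0]), requires_grad=True),
            b2=nn.zeros_param((1,)),
            w3=nn.he_normal(rng, (1, 1, kernel, kernel), kernel * kernel),
            b3=nn.zeros_param((1,)),
        )

    def tensors(self):
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2,
                "w3": self.w3, "b3": self.b3}


def _ensure_batched(x):
    x = x if isinstance(x, Tensor) else Tensor(x)
    if x.ndim == 3:
        return ad.reshape(x, (1,) + tuple(x.shape)), True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected a C×H×W or B×C×H×W tensor, got shape {x.shape}")


def channel_attention(x, p: ChannelAttentionParams):
    """Y_c = sigma(W2 relu(W1 (GAP_c + GMP_c))) * X_c."""
    x, squeeze = _ensure_batched(x)
    if p.w1.shape[1] != x.shape[1]:
        raise ValueError(
            f"channel_attention: input has {x.shape[1]} channels, params expect {p.w1.shape[1]}")
    pooled = nn.global_avg_pool(x) + nn.global_max_pool(x)           # (B, C)
    a = ad.sigmoid(nn.linear(ad.relu(nn.linear(pooled, p.w1, p.b1)), p.w2, p.b2))
    y = ad.mul(x, ad.reshape(a, (x.shape[0], x.shape[1], 1, 1)))
    return ad.reshape(y, y.shape[1:]) if squeeze else y


def spatial_attention(x, p: SpatialAttentionParams):
    """A = sigma(W3 relu(W1·GAP + W2·GMP)); Y_c = A ⊙ X_c."""
    x, squeeze = _ensure_batched(x)
    b, c, h, w = x.shape
    gap = ad.mean_(x, axis=1, keepdims=True)                         # (B,1,H,W)
    gmp = ad.reshape(ad.max_(x, axis=1), (b, 1, h, w))
    pre = ad.relu(ad.mul(gap, ad.reshape(p.w1, (1, 1, 1, 1)))
                  + ad.reshape(p.b1, (1, 1, 1, 1))
                  + ad.mul(gmp, ad.reshape(p.w2, (1, 1, 1, 1)))
                  + ad.reshape(p.b2, (1, 1, 1, 1)))
    k = p.w3.shape[-1]
    amap = ad.sigmoid(nn.conv2d(pre, p.w3, p.b3, padding=k // 2))    # (B,1,H,W)
    y = ad.mul(x, amap)
    return ad.reshape(y, y.shape[1:]) if squeeze else y


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``cells`` lists (in, out) channel pairs per attention-convolution cell;
    the default plan 128→64→64→32 suits a 128-channel 33×33 spectrogram
    stack, whose spatial size survives three 2×2 poolings as 33→16→8→4.
    """

    in_channels: int = 128
    n_classes: int = 8
    cells: tuple = ((128, 64), (64, 64), (64, 32))
    kernel: int = 3          # conv kernel K1 (padding kernel//2)
    pool: int = 2            # max-pool kernel/stride K2
    variant: str = "csac"
    reduction: int = 4       # channel-attention bottleneck ratio
    sam_kernel: int = 7      # spatial-attention conv kernel
    head_pool: tuple = (4, 4)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.cells[0][0] != self.in_channels:
            raise ValueError("first cell input width must equal in_channels")
        for (_, c1), (c2, _) in zip(self.cells[:-1], self.cells[1:]):
            if c1 != c2:
                raise ValueError("cell channel plan must chain")

    @classmethod
    def small(cls, in_channels, n_classes, variant="csac", width=8):
        """Compact plan for small synthetic profiles and tests."""
        cells = ((in_channels, width), (width, width), (width, width))
        return cls(in_channels=in_channels, n_classes=n_classes, cells=cells,
                   variant=variant, reduction=min(4, width))

    def to_json(self):
        return json.dumps({
            "in_channels": self.in_channels, "n_classes": self.n_classes,
            "cells": [list(c) for c in self.cells], "kernel": self.kernel,
            "pool": self.pool, "variant": self.variant, "reduction": self.reduction,
            "sam_kernel": self.sam_kernel, "head_pool": list(self.head_pool)})

    @classmethod
    def from_json(cls, s):
        d = json.loads(s)
        d["cells"] = tuple(tuple(c) for c in d["cells"])
        d["head_pool"] = tuple(d["head_pool"])
        return cls(**d)


class CSACNet:
    """The attention CNN with a flat, named parameter set.

    ``forward_logits`` accepts an optional parameter override (a dict with
    the same keys as ``self.params``) so adapted parameters produced by the
    meta-learner's inner loop can be evaluated without mutating the model.
    """

    def __init__(self, config: NetworkConfig, seed=0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: OrderedDict[str, Tensor] = OrderedDict()
        self.bn_running = {}
        cfg = config
        for i, (c1, c2) in enumerate(cfg.cells):
            pre = f"cell{i}"
            k = cfg.kernel
            self._register(f"{pre}.conv.w", nn.he_normal(rng, (c2, c1, k, k), c1 * k * k))
            self._register(f"{pre}.conv.b", nn.zeros_param((c2,)))
            use_cam = cfg.variant in ("csac", "cac")
            use_sam = cfg.variant in ("csac", "sac")
            if use_cam:
                for n, t in ChannelAttentionParams.init(rng, c2, cfg.reduction).tensors().items():
                    self._register(f"{pre}.cam.{n}", t)
            if use_sam:
                for n, t in SpatialAttentionParams.init(rng, cfg.sam_kernel).tensors().items():
                    self._register(f"{pre}.sam.{n}", t)
            if cfg.variant == "cnn":
                # one conventional conv replaces the whole attention module
                self._register(f"{pre}.repl.w", nn.he_normal(rng, (c2, 3, 3), 9))
                self._register(f"{pre}.repl.b", nn.zeros_param((c2,)))
            elif not use_cam:      # sac: conv in place of channel attention
                self._register(f"{pre}.repl_cam.w", nn.he_normal(rng, (c2, 3, 3), 9))
                self._register(f"{pre}.repl_cam.b", nn.zeros_param((c2,)))
            elif not use_sam:      # cac: conv in place of spatial attention
                self._register(f"{pre}.repl_sam.w", nn.he_normal(rng, (c2, 3, 3), 9))
                self._register(f"{pre}.repl_sam.b", nn.zeros_param((c2,)))
            self._register(f"{pre}.bn.gamma", nn.ones_param((c2,)))
            self._register(f"{pre}.bn.beta", nn.zeros_param((c2,)))
            self.bn_running[f"{pre}.bn"] = {"mean": np.zeros(c2), "var": np.ones(c2)}
        feat = cfg.cells[-1][1] * cfg.head_pool[0] * cfg.head_pool[1]
        self._register("head.w", nn.he_normal(rng, (cfg.n_classes, feat), feat))
        self._register("head.b", nn.zeros_param((cfg.n_classes,)))

    def _register(self, name, tensor):
        self.params[name] = tensor

    # -- forward -------------------------------------------------------

    def _cam(self, pre, p):
        return ChannelAttentionParams(p[f"{pre}.cam.w1"], p[f"{pre}.cam.b1"],
                                      p[f"{pre}.cam.w2"], p[f"{pre}.cam.b2"])

    def _sam(self, pre, p):
        return SpatialAttentionParams(p[f"{pre}.sam.w1"], p[f"{pre}.sam.b1"],
                                      p[f"{pre}.sam.w2"], p[f"{pre}.sam.b2"],
                                      p[f"{pre}.sam.w3"], p[f"{pre}.sam.b3"])

    def forward_logits(self, x, params=None, train=True):
        p = self.params if params is None else params
        cfg = self.config
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim == 3:
            x = ad.reshape(x, (1,) + tuple(x.shape))
        if x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, network expects {cfg.in_channels}")
        for i in range(len(cfg.cells)):
            pre = f"cell{i}"
            x = nn.conv2d(x, p[f"{pre}.conv.w"], p[f"{pre}.conv.b"],
                          padding=cfg.kernel // 2)
            if cfg.variant == "cnn":
                x = nn.depthwise_conv2d(x, p[f"{pre}.repl.w"], p[f"{pre}.repl.b"])
            else:
                if cfg.variant in ("csac", "cac"):
                    x = channel_attention(x, self._cam(pre, p))
                else:
                    x = nn.depthwise_conv2d(x, p[f"{pre}.repl_cam.w"], p[f"{pre}.repl_cam.b"])
                if cfg.variant in ("csac", "sac"):
                    x = spatial_attention(x, self._sam(pre, p))
                else:
                    x = nn.depthwise_conv2d(x, p[f"{pre}.repl_sam.w"], p[f"{pre}.repl_sam.b"])
            x = nn.batch_norm2d(x, p[f"{pre}.bn.gamma"], p[f"{pre}.bn.beta"],
                                self.bn_running[f"{pre}.bn"], train)
            x = ad.relu(x)
            x = nn.max_pool2d(x, cfg.pool)
        x = nn.avg_pool_to(x, cfg.head_pool)
        b = x.shape[0]
        x = ad.reshape(x, (b, -1))
        return nn.linear(x, p["head.w"], p["head.b"])

    def forward(self, x, params=None, train=False):
        """Class probabilities (rows sum to 1)."""
        return nn.softmax(self.forward_logits(x, params=params, train=train))

    def predict(self, x, params=None):
        with ad.no_grad():
            return np.argmax(self.forward_logits(x, params=params, train=False).data, axis=1)

    # -- bookkeeping ---------------------------------------------------

    def parameter_count(self):
        return int(sum(p.size for p in self.params.values()))

    def clone_params(self):
        return OrderedDict((k, Tensor(p.data.copy(), requires_grad=True))
                           for k, p in self.params.items())

    def set_params(self, params):
        for k, p in self.params.items():
            src = params[k]
            p.data = (src.data if isinstance(src, Tensor) else np.asarray(src)).copy()

    def describe(self):
        lines = [f"variant={self.config.variant}  parameters={self.parameter_count()}"]
        for name, p in self.params.items():
            lines.append(f"  {name:<20s} {p.shape}")
        return "\n".join(lines)

    def save(self, path):
        arrays = {f"param::{k}": p.data for k, p in self.params.items()}
        for bn, st in self.bn_running.items():
            arrays[f"running::{bn}::mean"] = st["mean"]
            arrays[f"running::{bn}::var"] = st["var"]
        np.savez(path, __config__=np.array(self.config.to_json()), **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as z:
            cfg = NetworkConfig.from_json(str(z["__config__"]))
            net = cls(cfg)
            for key in z.files:
                if key.startswith("param::"):
                    net.params[key[len("param::"):]].data = z[key].copy()
                elif key.startswith("running::"):
                    _, bn, stat = key.split("::")
                    net.bn_running[bn][stat] = z[key].copy()
        return net


def cross_entropy(pred, truth, eps=1e-12):
    """−Σ y_i log(ŷ_i) for probability predictions.

    ``pred`` is a probability vector (or a batch of rows summing to 1);
    ``truth`` is one-hot or an integer label (or batch thereof). Predicted
    probabilities are clamped at ``eps`` so a zero on the true class yields a
    large finite loss. Returns the mean over the batch.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.asarray(truth)
    if truth.ndim <= 1 and truth.size == pred.shape[0]:
        truth = nn.one_hot(truth.ravel(), pred.shape[1])
    truth = np.atleast_2d(truth)
    if truth.shape != pred.shape:
        raise ValueError("truth shape does not match predictions")
    return float(np.mean(-np.sum(truth * np.log(np.clip(pred, eps, None)), axis=1)))
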