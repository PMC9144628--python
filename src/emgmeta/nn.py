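"""Neural-network building blocks on top of the autodiff engine.

Convolution is expressed as im2col (a constant-index gather) followed by a
matmul, so every layer — and therefore the whole network — is differentiable
to second order, as the meta-learner requires. Layers are plain functions
taking parameter tensors explicitly; this functional style is what lets the
inner adaptation loop evaluate the network under fast-adapted parameters
without touching the stored ones.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_IM2COL_CACHE: dict = {}
_IM2COL_CACHE_MAX_ENTRIES = 3 * 10 ** 7  # total cached index elements


def _im2col_index(b, c, h, w, k, stride):
    """Flat gather indices turning a whole (B,C,H,W) batch into a
    (C·k·k, B·OH·OW) patch matrix in one gather, with the cached sparse
    scatter matrix for the adjoint.

    Folding the batch into the index keeps both the patch matrix and the
    convolution output contiguous, so each conv is a single GEMM with no
    large transposes. The cache is capped by total index size (entries are
    ~24 bytes per element with their scatter matrices) and evicts in FIFO
    order when a workload mixes many batch shapes.
    """
    key = (b, c, h, w, k, stride)
    hit = _IM2COL_CACHE.get(key)
    if hit is not None:
        return hit
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    ci = np.arange(c)[:, None, None, None, None]
    ki = np.arange(k)[None, :, None, None, None]
    kj = np.arange(k)[None, None, :, None, None]
    oi = np.arange(oh)[None, None, None, :, None]
    oj = np.arange(ow)[None, None, None, None, :]
    base = (ci * h * w + (oi * stride + ki) * w + (oj * stride + kj))
    base = base.reshape(c * k * k, oh * ow)
    offsets = np.arange(b) * (c * h * w)
    idx = (base[:, None, :] + offsets[None, :, None]).ravel()
    smat = ad.scatter_matrix(idx, b * c * h * w)
    total = sum(len(v[0]) for v in _IM2COL_CACHE.values()) + len(idx)
    while _IM2COL_CACHE and total > _IM2COL_CACHE_MAX_ENTRIES:
        oldest = next(iter(_IM2COL_CACHE))
        total -= len(_IM2COL_CACHE.pop(oldest)[0])
    _IM2COL_CACHE[key] = (idx, smat, oh, ow)
    return idx, smat, oh, ow


def _im2col(x, k, stride):
    """(B,C,H,W) -> (C·k·k, B·OH·OW) patch matrix plus output dims."""
    b, c, h, w = x.shape
    idx, smat, oh, ow = _im2col_index(b, c, h, w, k, stride)
    xf = ad.reshape(x, (1, b * c * h * w))
    cols = ad.take_cols(xf, idx, smat)
    return ad.reshape(cols, (c * k * k, b * oh * ow)), oh, ow


def conv2d(x, weight, bias=None, stride=1, padding=0):
    """2-D convolution (cross-correlation). weight: (Cout, Cin, k, k)."""
    if padding:
        x = ad.pad2d(x, padding)
    b = x.shape[0]
    cout, cin, k, _ = weight.shape
    if cin != x.shape[1]:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {cin}")
    cols, oh, ow = _im2col(x, k, stride)
    out = ad.matmul(ad.reshape(weight, (cout, cin * k * k)), cols)
    out = ad.transpose(ad.reshape(out, (cout, b, oh, ow)), (1, 0, 2, 3))
    if bias is not None:
        out = out + ad.reshape(bias, (1, cout, 1, 1))
    return out


def depthwise_conv2d(x, weight, bias=None, padding=1):
    """Per-channel k×k convolution. weight: (C, k, k)."""
    c, k, _ = weight.shape
    if c != x.shape[1]:
        raise ValueError("depthwise_conv2d: channel mismatch")
    if padding:
        x = ad.pad2d(x, padding)
    b, _, h, w = x.shape
    cols, oh, ow = _im2col(x, k, 1)                       # (C·kk, B·OH·OW)
    cols = ad.reshape(cols, (c, k * k, b * oh * ow))
    out = ad.einsum2("ck,ckt->ct", ad.reshape(weight, (c, k * k)), cols)
    out = ad.transpose(ad.reshape(out, (c, b, oh, ow)), (1, 0, 2, 3))
    if bias is not None:
        out = out + ad.reshape(bias, (1, c, 1, 1))
    return out


def max_pool2d(x, kernel=2):
    """Non-overlapping max pooling; trailing rows/cols are dropped (floor)."""
    b, c, h, w = x.shape
    oh, ow = h // kernel, w // kernel
    if oh < 1 or ow < 1:
        raise ValueError(f"max_pool2d: spatial dims {h}x{w} smaller than kernel {kernel}")
    x = ad.crop2d(x, oh * kernel, ow * kernel)
    x = ad.reshape(x, (b, c, oh, kernel, ow, kernel))
    x = ad.max_(x, axis=5)
    x = ad.max_(x, axis=3)
    return x


def avg_pool_to(x, out_hw):
    """Average-pool to a fixed spatial size (kernel = floor(dim/target))."""
    b, c, h, w = x.shape
    th, tw = out_hw
    kh, kw = max(h // th, 1), max(w // tw, 1)
    x = ad.crop2d(x, th * kh, tw * kw)
    x = ad.reshape(x, (b, c, th, kh, tw, kw))
    return ad.mean_(ad.mean_(x, axis=5), axis=3)


def linear(x, weight, bias=None):
    """x: (B, Fin), weight: (Fout, Fin)."""
    out = ad.matmul(x, ad.transpose(weight, (1, 0)))
    if bias is not None:
        out = out + ad.reshape(bias, (1, weight.shape[0]))
    return out


def global_avg_pool(x):
    """(B,C,H,W) -> (B,C)."""
    return ad.mean_(x, axis=(2, 3))


def global_max_pool(x):
    """(B,C,H,W) -> (B,C)."""
    b, c, h, w = x.shape
    return ad.max_(ad.reshape(x, (b, c, h * w)), axis=2)


def batch_norm2d(x, gamma, beta, running, train, momentum=0.1, eps=1e-5):
    """Per-channel batch normalization.

    ``running`` is a mutable dict with 'mean' and 'var' numpy arrays, updated
    in place in training mode and used as constants in eval mode.
    """
    c = x.shape[1]
    if train:
        m = ad.mean_(x, axis=(0, 2, 3), keepdims=True)
        v = ad.mean_(ad.mul(x - m, x - m), axis=(0, 2, 3), keepdims=True)
        n = x.shape[0] * x.shape[2] * x.shape[3]
        running["mean"] = (1 - momentum) * running["mean"] + momentum * m.data.ravel()
        unbiased = v.data.ravel() * (n / max(n - 1, 1))
        running["var"] = (1 - momentum) * running["var"] + momentum * unbiased
    else:
        m = Tensor(running["mean"].reshape(1, c, 1, 1))
        v = Tensor(running["var"].reshape(1, c, 1, 1))
    xn = ad.mul(x - m, ad.pow_(v + eps, -0.5))
    return ad.mul(xn, ad.reshape(gamma, (1, c, 1, 1))) + ad.reshape(beta, (1, c, 1, 1))


def softmax(logits):
    """Row softmax of a (B, n) logit matrix."""
    shift = logits - Tensor(np.max(logits.data, axis=1, keepdims=True))
    e = ad.exp(shift)
    return ad.mul(e, ad.pow_(ad.sum_(e, axis=1, keepdims=True), -1.0))


def log_softmax(logits):
    shift = logits - Tensor(np.max(logits.data, axis=1, keepdims=True))
    lse = ad.log(ad.sum_(ad.exp(shift), axis=1, keepdims=True))
    return shift - lse


def softmax_cross_entropy(logits, onehot):
    """Mean cross-entropy of (B, n) logits against a constant one-hot matrix."""
    logp = log_softmax(logits)
    b = logits.shape[0]
    return ad.mul(ad.sum_(ad.mul(Tensor(onehot), logp)), ad.as_tensor(-1.0 / b))


def one_hot(labels, n_classes):
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


# -- initialization ----------------------------------------------------

def he_normal(rng, shape, fan_in):
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


def zeros_param(shape):
    return Tensor(np.zeros(shape), requires_grad=True)


def ones_param(shape):
    return Tensor(np.ones(shape), requires_grad=True)


# -- optimizers --------------------------------------------------------

class SGD:
    def __init__(self, params: OrderedDict, lr, weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def step(self, grads: dict):
        for name, p in self.params.items():
            g = grads[name]
            g = g if isinstance(g, np.ndarray) else g.data
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            p.data -= self.lr * g


class Adam:
    """Adam with optional coupled L2 weight decay (added to the gradient)."""

    def __init__(self, params: OrderedDict, lr, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, grads: dict):
        self.t += 1
        for name, p in self.params.items():
            g = grads[name]
            g = g if isinstance(g, np.ndarray) else g.data
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
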