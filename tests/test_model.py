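"""The attention CNN: attention algebra, cell shapes, variants, loss,
and a full-network gradient check."""

import numpy as np
import pytest

from emgmeta import (CSACNet, ChannelAttentionParams, NetworkConfig,
                     SpatialAttentionParams, channel_attention, cross_entropy,
                     spatial_attention)
from emgmeta import autodiff as ad
from emgmeta import nn


def _zero_cam(c, r=2):
    h = c // r
    return ChannelAttentionParams(
        w1=ad.Tensor(np.zeros((h, c)), requires_grad=True),
        b1=ad.Tensor(np.zeros(h), requires_grad=True),
        w2=ad.Tensor(np.zeros((c, h)), requires_grad=True),
        b2=ad.Tensor(np.zeros(c), requires_grad=True))


def _zero_sam(k=3):
    z = lambda *s: ad.Tensor(np.zeros(s), requires_grad=True)
    return SpatialAttentionParams(z(1), z(1), z(1), z(1), z(1, 1, k, k), z(1))


def test_zero_weight_attention_scales_by_exactly_half(rng):
    x = rng.normal(size=(2, 4, 3, 3))
    y_cam = channel_attention(ad.Tensor(x), _zero_cam(4))
    y_sam = spatial_attention(ad.Tensor(x), _zero_sam())
    assert np.array_equal(y_cam.data, 0.5 * x)
    assert np.array_equal(y_sam.data, 0.5 * x)


def test_attention_strictly_shrinks_nonzero_entries(rng):
    x = rng.normal(size=(4, 5, 5))
    cam = ChannelAttentionParams.init(np.random.default_rng(1), 4, 2)
    sam = SpatialAttentionParams.init(np.random.default_rng(1), 7)
    for y in (channel_attention(ad.Tensor(x), cam),
              spatial_attention(ad.Tensor(x), sam)):
        nz = x != 0
        assert np.all(np.abs(y.data[nz]) < np.abs(x[nz]))
        assert np.all(np.abs(y.data) <= np.abs(x))


def test_channel_attention_matches_hand_arithmetic():
    """2-channel 2×2 input, 1-dim bottleneck, checked against scalar
    arithmetic done independently with numpy."""
    x = np.array([[[1.0, 2.0], [3.0, 4.0]],
                  [[-1.0, 0.0], [1.0, 2.0]]])
    w1 = np.array([[0.5, -0.25]])
    b1 = np.array([0.1])
    w2 = np.array([[1.0], [-2.0]])
    b2 = np.array([0.2, -0.3])
    p = ChannelAttentionParams(*(ad.Tensor(a, requires_grad=True)
                                 for a in (w1, b1, w2, b2)))
    pooled = x.mean(axis=(1, 2)) + x.max(axis=(1, 2))      # GAP + GMP
    hidden = np.maximum(w1 @ pooled + b1, 0.0)
    att = 1.0 / (1.0 + np.exp(-(w2 @ hidden + b2)))
    expected = x * att[:, None, None]
    y = channel_attention(ad.Tensor(x), p)
    assert np.allclose(y.data, expected, atol=1e-12)


def test_spatial_attention_matches_hand_arithmetic():
    """Single-channel 2×2 input with unit 1×1 maps: the attention map is
    sigmoid(relu(gap + gmp)) pixelwise."""
    x = np.array([[[1.0, -2.0], [0.5, 3.0]]])
    p = SpatialAttentionParams(
        w1=ad.Tensor([1.0], requires_grad=True), b1=ad.Tensor([0.0], requires_grad=True),
        w2=ad.Tensor([1.0], requires_grad=True), b2=ad.Tensor([0.0], requires_grad=True),
        w3=ad.Tensor(np.ones((1, 1, 1, 1)), requires_grad=True),
        b3=ad.Tensor([0.0], requires_grad=True))
    amap = 1.0 / (1.0 + np.exp(-np.maximum(x[0] + x[0], 0.0)))  # gap=gmp=x
    y = spatial_attention(ad.Tensor(x), p)
    assert np.allclose(y.data, x * amap, atol=1e-12)


def test_attention_channel_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        channel_attention(ad.Tensor(rng.normal(size=(8, 3, 3))), _zero_cam(4))


def test_cell_output_shapes_default_plan(rng):
    net = CSACNet(NetworkConfig(), seed=0)
    x = rng.normal(size=(2, 128, 33, 33))
    probs = net.forward(x, train=True)
    assert probs.shape == (2, 8)
    assert np.allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs.data >= 0)


@pytest.mark.parametrize("variant", ["csac", "sac", "cac", "cnn"])
def test_variants_preserve_shapes(variant, rng):
    net = CSACNet(NetworkConfig.small(8, 5, variant=variant), seed=0)
    out = net.forward_logits(rng.normal(size=(3, 8, 33, 33)), train=True)
    assert out.shape == (3, 5)


def test_variant_parameter_counts_within_20_percent():
    counts = [CSACNet(NetworkConfig(variant=v)).parameter_count()
              for v in ("csac", "sac", "cac", "cnn")]
    assert (max(counts) - min(counts)) / min(counts) < 0.20


def test_identical_inputs_identical_rows_eval_mode(rng):
    net = CSACNet(NetworkConfig.small(4, 3), seed=0)
    x = np.tile(rng.normal(size=(1, 4, 33, 33)), (4, 1, 1, 1))
    probs = net.forward(x, train=False)
    assert np.allclose(probs.data, probs.data[0], atol=1e-12)


def test_permuting_head_permutes_outputs(rng):
    net = CSACNet(NetworkConfig.small(4, 4), seed=0)
    x = rng.normal(size=(2, 4, 33, 33))
    base = net.forward(x, train=False).data
    perm = np.array([2, 0, 3, 1])
    net.params["head.w"].data = net.params["head.w"].data[perm]
    net.params["head.b"].data = net.params["head.b"].data[perm]
    assert np.allclose(net.forward(x, train=False).data, base[:, perm], atol=1e-9)


def test_cross_entropy_values():
    assert cross_entropy([1.0, 0.0, 0.0], [1.0, 0.0, 0.0]) == 0.0
    assert np.isclose(cross_entropy(np.full(8, 1 / 8), np.eye(8)[0]), np.log(8))
    assert np.isclose(cross_entropy([0.7, 0.2, 0.1], 0), -np.log(0.7))
    # zero mass on the true class is clamped, not infinite
    assert np.isfinite(cross_entropy([0.0, 1.0], [1.0, 0.0]))
    with pytest.raises(ValueError):
        cross_entropy([0.5, 0.5], [1.0, 0.0, 0.0])


def test_full_network_gradient_check(rng):
    """Analytic gradients of forward+loss match central finite differences
    on a tiny configuration."""
    cfg = NetworkConfig(in_channels=4, n_classes=2, cells=((4, 4),),
                        reduction=2, head_pool=(1, 1))
    net = CSACNet(cfg, seed=1)
    x = rng.normal(size=(3, 4, 5, 5))
    y = nn.one_hot([0, 1, 0], 2)

    def loss_value():
        return nn.softmax_cross_entropy(net.forward_logits(x, train=True), y).item()

    loss = nn.softmax_cross_entropy(net.forward_logits(x, train=True), y)
    grads = ad.grad(loss, list(net.params.values()))
    eps = 1e-6
    for (name, p), g in zip(net.params.items(), grads):
        num = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            p.data[i] += eps
            lp = loss_value()
            p.data[i] -= 2 * eps
            lm = loss_value()
            p.data[i] += eps
            num[i] = (lp - lm) / (2 * eps)
        denom = max(np.max(np.abs(num)), 1e-6)
        assert np.max(np.abs(num - g.data)) / denom < 1e-4, name


def test_checkpoint_roundtrip(tmp_path, rng):
    net = CSACNet(NetworkConfig.small(4, 3), seed=2)
    x = rng.normal(size=(2, 4, 33, 33))
    net.forward(x, train=True)  # move BN running stats off their init
    ref = net.forward(x, train=False).data
    net.save(tmp_path / "model.npz")
    loaded = CSACNet.load(tmp_path / "model.npz")
    assert np.allclose(loaded.forward(x, train=False).data, ref, atol=1e-12)
    assert loaded.config.variant == "csac"


def test_input_channel_mismatch_rejected(rng):
    net = CSACNet(NetworkConfig.small(8, 3), seed=0)
    with pytest.raises(ValueError):
        net.forward_logits(rng.normal(size=(1, 4, 33, 33)))
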