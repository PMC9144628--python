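"""MAML inner/outer loops: closed-form and finite-difference exactness,
identity properties, and chance-level behaviour."""

from collections import OrderedDict

import numpy as np
import pytest

from emgmeta import MetaConfig, Task, inner_adapt, meta_test, meta_train
from emgmeta import autodiff as ad
from emgmeta import nn
from emgmeta.episodes import task_stream


class TinyLinear:
    class _Cfg:
        n_classes = 3

    config = _Cfg()

    def __init__(self, seed=0, dim=4):
        rng = np.random.default_rng(seed)
        self.params = OrderedDict(
            w=ad.Tensor(rng.normal(size=(3, dim)) * 0.1, requires_grad=True),
            b=ad.Tensor(np.zeros(3), requires_grad=True))

    def forward_logits(self, x, params=None, train=True):
        p = self.params if params is None else params
        return nn.linear(ad.as_tensor(np.asarray(x, dtype=float)), p["w"], p["b"])

    def clone(self):
        m = TinyLinear()
        m.params = OrderedDict((k, ad.Tensor(v.data.copy(), requires_grad=True))
                               for k, v in self.params.items())
        return m


def _mk_task(rng, n=3, k=2, dim=4):
    xs = rng.normal(size=(n * k, dim))
    ys = np.repeat(np.arange(n), k)
    xq = rng.normal(size=(n * k, dim))
    return Task(xs, ys, xq, ys.copy(), np.arange(n),
                np.arange(n * k), np.arange(n * k) + 1000)


def test_quadratic_inner_step_closed_form():
    """One gradient step on L = 0.5 (theta - c)^2 gives theta - alpha(theta-c)
    to machine precision."""
    theta0, c, alpha = 3.0, 1.25, 0.1
    theta = ad.Tensor(theta0, requires_grad=True)
    loss = 0.5 * (theta - c) ** 2
    (g,) = ad.grad(loss, [theta])
    adapted = theta.data - alpha * g.data
    assert adapted == theta0 - alpha * (theta0 - c)


def test_inner_adapt_alpha_zero_is_identity(rng):
    m = TinyLinear(seed=1)
    task = _mk_task(rng)
    theta1 = inner_adapt(m, m.params, task.support_x, task.support_y,
                         alpha=0.0, steps=3, n_classes=3)
    for k in m.params:
        assert np.array_equal(theta1[k].data, m.params[k].data)


def test_inner_adapt_never_mutates_meta_parameters(rng):
    m = TinyLinear(seed=1)
    before = {k: v.data.copy() for k, v in m.params.items()}
    task = _mk_task(rng)
    inner_adapt(m, m.params, task.support_x, task.support_y, 0.5, 3, 3)
    for k in m.params:
        assert np.array_equal(m.params[k].data, before[k])


def test_inner_step_matches_finite_difference_gradient(rng):
    m = TinyLinear(seed=2)
    task = _mk_task(rng)
    alpha = 0.07
    theta1 = inner_adapt(m, m.params, task.support_x, task.support_y, alpha, 1, 3)
    # finite-difference gradient of the support loss
    onehot = nn.one_hot(task.support_y, 3)

    def loss():
        return nn.softmax_cross_entropy(
            m.forward_logits(task.support_x), onehot).item()

    eps = 1e-6
    for name, p in m.params.items():
        num = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            p.data[i] += eps
            lp = loss()
            p.data[i] -= 2 * eps
            lm = loss()
            p.data[i] += eps
            num[i] = (lp - lm) / (2 * eps)
        implied = (m.params[name].data - theta1[name].data) / alpha
        denom = max(np.max(np.abs(num)), 1e-8)
        assert np.max(np.abs(implied - num)) / denom < 1e-4


def test_fomaml_update_equals_hand_rolled_two_loop(rng):
    """meta_batch=1, SGD outer, first-order: the update is one SGD step on
    the query-loss gradient evaluated at the adapted parameters."""
    def softmax(z):
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def ce_grads(w, b, x, y):
        p = softmax(x @ w.T + b)
        p[np.arange(len(y)), y] -= 1
        p /= len(y)
        return p.T @ x, p.sum(axis=0)

    m = TinyLinear(seed=3)
    task = _mk_task(rng)
    alpha, beta = 0.05, 0.1
    w0, b0 = m.params["w"].data.copy(), m.params["b"].data.copy()
    gw, gb = ce_grads(w0, b0, task.support_x, task.support_y)
    w1, b1 = w0 - alpha * gw, b0 - alpha * gb
    qgw, qgb = ce_grads(w1, b1, task.query_x, task.query_y)
    cfg = MetaConfig(alpha=alpha, beta=beta, meta_batch=1, second_order=False,
                     outer_optimizer="sgd", grad_clip=None)
    meta_train(m, iter([task]), cfg, n_meta_batches=1)
    assert np.allclose(m.params["w"].data, w0 - beta * qgw, atol=1e-12)
    assert np.allclose(m.params["b"].data, b0 - beta * qgb, atol=1e-12)


def test_second_order_metagradient_matches_finite_differences(rng):
    """The outer gradient with second_order=True differentiates through the
    inner update (checked against FD of the full MAML objective)."""
    def softmax(z):
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def ce_grads(w, b, x, y):
        p = softmax(x @ w.T + b)
        p[np.arange(len(y)), y] -= 1
        p /= len(y)
        return p.T @ x, p.sum(axis=0)

    m = TinyLinear(seed=4)
    task = _mk_task(rng)
    alpha = 0.1

    def maml_objective(w, b):
        gw, gb = ce_grads(w, b, task.support_x, task.support_y)
        w1, b1 = w - alpha * gw, b - alpha * gb
        p = softmax(task.query_x @ w1.T + b1)
        return -np.mean(np.log(p[np.arange(len(task.query_y)), task.query_y]))

    theta1 = inner_adapt(m, m.params, task.support_x, task.support_y,
                         alpha, 1, 3, create_graph=True)
    qloss = nn.softmax_cross_entropy(
        m.forward_logits(task.query_x, params=theta1),
        nn.one_hot(task.query_y, 3))
    grads = ad.grad(qloss, list(m.params.values()))
    w = m.params["w"]
    num = np.zeros_like(w.data)
    eps = 1e-6
    it = np.nditer(w.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        w.data[i] += eps
        lp = maml_objective(w.data, m.params["b"].data)
        w.data[i] -= 2 * eps
        lm = maml_objective(w.data, m.params["b"].data)
        w.data[i] += eps
        num[i] = (lp - lm) / (2 * eps)
    assert np.max(np.abs(num - grads[0].data)) / np.max(np.abs(num)) < 1e-6


def test_alpha_zero_metagradient_is_plain_multitask_gradient(rng):
    """With alpha -> 0 the (second-order) meta-gradient collapses to the
    ordinary gradient of the query loss at theta."""
    m = TinyLinear(seed=7)
    task = _mk_task(rng)
    theta1 = inner_adapt(m, m.params, task.support_x, task.support_y,
                         alpha=0.0, steps=1, n_classes=3, create_graph=True)
    onehot = nn.one_hot(task.query_y, 3)
    meta_grads = ad.grad(
        nn.softmax_cross_entropy(m.forward_logits(task.query_x, params=theta1),
                                 onehot), list(m.params.values()))
    plain_grads = ad.grad(
        nn.softmax_cross_entropy(m.forward_logits(task.query_x), onehot),
        list(m.params.values()))
    for g_meta, g_plain in zip(meta_grads, plain_grads):
        assert np.allclose(g_meta.data, g_plain.data, atol=1e-12)


def test_beta_zero_leaves_parameters_unchanged(rng):
    m = TinyLinear(seed=5)
    before = {k: v.data.copy() for k, v in m.params.items()}
    tasks = [_mk_task(rng) for _ in range(4)]
    cfg = MetaConfig(alpha=0.1, beta=0.0, meta_batch=2, second_order=False,
                     outer_optimizer="sgd")
    meta_train(m, iter(tasks), cfg, n_meta_batches=2)
    for k in m.params:
        assert np.array_equal(m.params[k].data, before[k])


def test_meta_test_zero_steps_reports_unadapted_accuracy(rng):
    m = TinyLinear(seed=6)
    tasks = [_mk_task(rng) for _ in range(3)]
    cfg = MetaConfig(inner_steps_test=0)
    summary = meta_test(m, iter(tasks), cfg)
    assert len(summary["top1_mean_per_step"]) == 1
    assert summary["pre_adaptation_top1"] == summary["post_adaptation_top1"]


def test_meta_test_empty_stream_rejected():
    with pytest.raises(ValueError):
        meta_test(TinyLinear(), iter([]), MetaConfig())


def test_untrained_model_is_at_chance_on_5way_tasks(train_pool):
    """Step-0 query accuracy of a random network over many 5-way tasks is
    0.20 within binomial tolerance."""
    from emgmeta import CSACNet, NetworkConfig
    net = CSACNet(NetworkConfig.small(16, 5, width=4), seed=123)
    cfg = MetaConfig(inner_steps_test=0)
    summary = meta_test(net, task_stream(train_pool, 500, 5, 1, seed=11), cfg)
    assert abs(summary["pre_adaptation_top1"] - 0.20) <= 0.03


def test_meta_config_validation():
    with pytest.raises(ValueError):
        MetaConfig(meta_batch=0).validate()
    with pytest.raises(ValueError):
        MetaConfig(outer_optimizer="lbfgs").validate()
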