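"""Model-agnostic meta-learning (MAML) for few-shot subject adaptation.

Meta-training optimizes the network initialization so that one (or a few)
gradient steps on a new task's support set already classify its query set
well. Per meta-batch:

1. for each task, fast-adapt a copy of the parameters on the support loss:
   theta_i' = theta − alpha·∇_theta L_support(theta);
2. accumulate the query loss of the adapted parameters;
3. update theta with the outer optimizer on the mean query loss. With
   ``second_order=True`` the outer gradient differentiates through the inner
   update (true MAML); with ``False`` it is taken at theta_i' (first-order
   MAML), which is substantially cheaper and typically nearly as accurate.

Meta-testing adapts the learned initialization on each held-out task's
support set for a configurable number of steps and reports query accuracy
after every step, so both fixed-step and best-step summaries are available.

Any model exposing ``params`` (an ordered name→Tensor mapping) and
``forward_logits(x, params=..., train=...)`` can be meta-trained; the
attention CNN is the intended one.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .episodes import topk_accuracy

__all__ = ["MetaConfig", "AdaptationResult", "inner_adapt", "meta_train", "meta_test"]


@dataclass
class MetaConfig:
    alpha: float = 0.1            # inner (fast) learning rate
    beta: float = 0.001           # outer (meta) learning rate
    meta_batch: int = 8           # tasks per outer update
    inner_steps_train: int = 1
    inner_steps_test: int = 5
    outer_optimizer: str = "adam"
    second_order: bool = True
    grad_clip: float = 10.0   # global-norm clip of the meta-gradient; None disables
    beta_warmup: int = 0      # meta-batches of linear outer-lr warmup (0 = off)
    n_tasks: int = 20000
    seed: int = 0

    def validate(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("learning rates must be non-negative")
        if self.meta_batch < 1:
            raise ValueError("meta_batch must be >= 1")
        if self.outer_optimizer not in ("adam", "sgd"):
            raise ValueError("outer_optimizer must be 'adam' or 'sgd'")
        return self


@dataclass
class AdaptationResult:
    """Per-task record: query loss/accuracy after each inner step."""

    query_loss: list
    top1: list            # index s = accuracy after s adaptation steps
    topk: list
    k: int


def _task_loss(model, params, x, y, n_classes, train=True):
    logits = model.forward_logits(x, params=params, train=train)
    return nn.softmax_cross_entropy(logits, nn.one_hot(y, n_classes)), logits


def inner_adapt(model, params, support_x, support_y, alpha, steps,
                n_classes=None, create_graph=False):
    """``steps`` gradient-descent updates on the support loss.

    Returns a fresh parameter mapping; the input parameters are never
    mutated. With ``create_graph=True`` the result stays connected to the
    originals so an outer gradient can flow through the update.
    """
    if len(support_y) == 0:
        raise ValueError("support set is empty")
    n_classes = n_classes or model.config.n_classes
    theta = params
    names = list(params.keys())
    for _ in range(steps):
        loss, _ = _task_loss(model, theta, support_x, support_y, n_classes)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite support loss {loss.data!r}")
        grads = ad.grad(loss, [theta[k] for k in names], create_graph=create_graph)
        if create_graph:
            theta = OrderedDict(
                (k, theta[k] - ad.as_tensor(alpha) * g) for k, g in zip(names, grads))
        else:
            theta = OrderedDict(
                (k, Tensor(theta[k].data - alpha * g.data, requires_grad=True))
                for k, g in zip(names, grads))
    return theta


def _evaluate(model, params, x, y, n_classes):
    with ad.no_grad():
        logits = model.forward_logits(x, params=params, train=True)
        loss = nn.softmax_cross_entropy(logits, nn.one_hot(y, n_classes)).item()
    acc = topk_accuracy(logits.data, y, 1)
    return loss, acc, logits.data


def meta_train(model, tasks, cfg: MetaConfig, n_meta_batches=None, callback=None,
               val_tasks=None, val_every=25, val_steps=3):
    """MAML training over a task iterable; returns a per-meta-batch log.

    ``tasks`` is consumed meta_batch at a time; ``n_meta_batches`` caps the
    number of outer updates (otherwise the iterable is exhausted).

    If ``val_tasks`` (a list of held-out-subject tasks) is given, adapted
    query accuracy on them (``val_steps`` adaptation steps) is evaluated
    every ``val_every`` meta-batches and the best-scoring parameters are
    restored into the model at the end — meta-validation model selection.
    """
    cfg.validate()
    names = list(model.params.keys())
    n_classes = model.config.n_classes
    if cfg.outer_optimizer == "adam":
        opt = nn.Adam(model.params, lr=cfg.beta)
    else:
        opt = nn.SGD(model.params, lr=cfg.beta)
    log = []
    best_val, best_params = -1.0, None

    def _validate():
        nonlocal best_val, best_params
        accs = []
        for vt in val_tasks:
            th = inner_adapt(model, model.params, vt.support_x, vt.support_y,
                             cfg.alpha, max(val_steps, 1), n_classes)
            _, acc, _ = _evaluate(model, th, vt.query_x, vt.query_y, n_classes)
            accs.append(acc)
        val_acc = float(np.mean(accs))
        if val_acc > best_val:
            best_val = val_acc
            best_params = OrderedDict(
                (k, Tensor(p.data.copy(), requires_grad=True))
                for k, p in model.params.items())
        return val_acc

    it = iter(tasks)
    batch_idx = 0
    while n_meta_batches is None or batch_idx < n_meta_batches:
        batch = []
        for _ in range(cfg.meta_batch):
            try:
                batch.append(next(it))
            except StopIteration:
                break
        if not batch:
            break
        accum = {k: np.zeros_like(p.data) for k, p in model.params.items()}
        qlosses, qaccs = [], []
        for task in batch:
            theta1 = inner_adapt(model, model.params, task.support_x, task.support_y,
                                 cfg.alpha, cfg.inner_steps_train, n_classes,
                                 create_graph=cfg.second_order)
            qloss, qlogits = _task_loss(model, theta1, task.query_x, task.query_y,
                                        n_classes)
            if not np.isfinite(qloss.data):
                raise FloatingPointError(
                    f"meta-batch {batch_idx}: non-finite query loss; aborting "
                    f"(last logged batches: {log[-3:]})")
            wrt = [model.params[k] for k in names] if cfg.second_order \
                else [theta1[k] for k in names]
            grads = ad.grad(qloss, wrt)
            for k, g in zip(names, grads):
                accum[k] += g.data / len(batch)
            qlosses.append(qloss.item())
            qaccs.append(topk_accuracy(qlogits.data, task.query_y, 1))
        if cfg.beta_warmup:
            opt.lr = cfg.beta * min(1.0, (batch_idx + 1) / cfg.beta_warmup)
        if cfg.grad_clip:
            # meta-gradients through an aggressive inner step can spike;
            # global-norm clipping keeps the outer update bounded
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in accum.values()))
            if norm > cfg.grad_clip:
                scale = cfg.grad_clip / norm
                accum = {k: g * scale for k, g in accum.items()}
        opt.step(accum)
        entry = {"meta_batch": batch_idx, "query_loss": float(np.mean(qlosses)),
                 "query_acc": float(np.mean(qaccs))}
        if val_tasks and (batch_idx + 1) % val_every == 0:
            entry["val_acc"] = _validate()
        log.append(entry)
        if callback is not None:
            callback(entry, model)
        batch_idx += 1
    if val_tasks:
        if (batch_idx % val_every) != 0 or not log or "val_acc" not in log[-1]:
            _validate()
        if best_params is not None:
            for k, p in model.params.items():
                p.data = best_params[k].data
    return log


def meta_test(model, tasks, cfg: MetaConfig, k=None):
    """Adapt on each test task's support set, scoring the query set after
    every inner step.

    Returns per-step mean ± SD of top-1 (and top-k) query accuracy across
    tasks, plus the best-step summary and the per-task records.
    """
    cfg.validate()
    n_classes = model.config.n_classes
    k = k if k is not None else min(5, n_classes)
    results = []
    for task in tasks:
        theta = model.params
        ql0, acc0, logits0 = _evaluate(model, theta, task.query_x, task.query_y,
                                       n_classes)
        rec = AdaptationResult(query_loss=[ql0], top1=[acc0],
                               topk=[topk_accuracy(logits0, task.query_y, k)], k=k)
        for _ in range(cfg.inner_steps_test):
            theta = inner_adapt(model, theta, task.support_x, task.support_y,
                                cfg.alpha, 1, n_classes, create_graph=False)
            ql, acc, logits = _evaluate(model, theta, task.query_x, task.query_y,
                                        n_classes)
            rec.query_loss.append(ql)
            rec.top1.append(acc)
            rec.topk.append(topk_accuracy(logits, task.query_y, k))
        results.append(rec)
    if not results:
        raise ValueError("empty test task stream")
    top1 = np.array([r.top1 for r in results])      # tasks × (steps+1)
    topk = np.array([r.topk for r in results])
    mean_steps = top1.mean(axis=0)
    best_step = int(np.argmax(mean_steps))
    return {
        "n_tasks": len(results),
        "top1_mean_per_step": mean_steps.tolist(),
        "top1_sd_per_step": top1.std(axis=0).tolist(),
        "topk_mean_per_step": topk.mean(axis=0).tolist(),
        "pre_adaptation_top1": float(mean_steps[0]),
        "post_adaptation_top1": float(mean_steps[-1]),
        "best_step": best_step,
        "best_step_top1": float(mean_steps[best_step]),
        "results": results,
    }
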