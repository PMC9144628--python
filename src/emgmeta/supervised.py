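"""Conventional supervised training and the pretrain-then-transfer probe.

Within-corpus classification pools samples across subjects, splits them
6:2:2 (train/validation/test, stratified by class) and minimizes the
cross-entropy with Adam; the learning rate drops from 1e-3 to 1e-4 halfway
through training and the checkpoint with the best validation accuracy is
returned.

``pretrain_transfer_eval`` quantifies why this is not enough for new users:
a model trained on one set of subjects is evaluated frozen on held-out
subjects. With real inter-subject variability (or the generator's subject
gain/shift perturbations) the frozen accuracy collapses far below the
within-subjects validation accuracy — the gap meta-learning closes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .episodes import topk_accuracy

__all__ = ["TrainConfig", "split_dataset", "train_supervised", "evaluate",
           "pretrain_transfer_eval"]


@dataclass
class TrainConfig:
    lr: float = 0.001
    lr_after_drop: float = 0.0001
    lr_drop_epoch: int = 150
    epochs: int = 300
    batch: int = 64
    weight_decay: float = 0.0001
    optimizer: str = "adam"
    split: tuple = (0.6, 0.2, 0.2)
    seed: int = 0

    def validate(self):
        if abs(sum(self.split) - 1.0) > 1e-9 or any(r < 0 for r in self.split):
            raise ValueError("split ratios must be non-negative and sum to 1")
        if self.epochs < 0 or self.batch < 1:
            raise ValueError("invalid epochs/batch")
        return self


def split_dataset(x, y, ratios=(0.6, 0.2, 0.2), seed=0, stratify=True):
    """Stratified random partition into (train, val, test) index arrays.

    Per class, samples are shuffled and cut at the cumulative ratios, so
    pool sizes per class follow the ratios up to rounding and every
    non-empty pool sees every class. A class must have at least as many
    samples as there are non-empty pools.
    """
    y = np.asarray(y, dtype=int)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    n_pools = sum(r > 0 for r in ratios)
    pools = ([], [], [])
    groups = [np.flatnonzero(y == c) for c in np.unique(y)] if stratify \
        else [np.arange(len(y))]
    for members in groups:
        if stratify and len(members) < n_pools:
            raise ValueError(
                f"a class has {len(members)} samples; cannot stratify into "
                f"{n_pools} pools")
        perm = rng.permutation(members)
        cuts = np.floor(np.cumsum(ratios)[:2] * len(perm)).astype(int)
        parts = np.split(perm, cuts)
        for pool, part in zip(pools, parts):
            pool.extend(part.tolist())
    return tuple(np.sort(np.array(p, dtype=int)) for p in pools)


def evaluate(model, x, y, params=None, batch=64):
    """Mean cross-entropy and top-1 accuracy in eval mode (running BN stats)."""
    y = np.asarray(y, dtype=int)
    losses, hits = [], 0
    with ad.no_grad():
        for i in range(0, len(y), batch):
            xb, yb = x[i:i + batch], y[i:i + batch]
            logits = model.forward_logits(xb, params=params, train=False)
            losses.append(nn.softmax_cross_entropy(
                logits, nn.one_hot(yb, model.config.n_classes)).item() * len(yb))
            hits += topk_accuracy(logits.data, yb, 1) * len(yb)
    return float(np.sum(losses) / len(y)), float(hits / len(y))


def train_supervised(model, train_xy, val_xy, cfg: TrainConfig):
    """Minimize cross-entropy on the train pool; keep the best-validation
    checkpoint. Returns (best_params, history)."""
    cfg.validate()
    xtr, ytr = train_xy
    xval, yval = val_xy
    if len(ytr) == 0 or len(yval) == 0:
        raise ValueError("train and validation pools must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    n_classes = model.config.n_classes
    if cfg.optimizer == "adam":
        opt = nn.Adam(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    else:
        opt = nn.SGD(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = []
    best = {"val_acc": -1.0, "params": model.clone_params()}
    names = list(model.params.keys())
    for epoch in range(cfg.epochs):
        lr = cfg.lr if epoch < cfg.lr_drop_epoch else cfg.lr_after_drop
        opt.lr = lr
        order = rng.permutation(len(ytr))
        ep_loss, ep_hits = 0.0, 0.0
        for i in range(0, len(order), cfg.batch):
            sel = order[i:i + cfg.batch]
            logits = model.forward_logits(xtr[sel], train=True)
            loss = nn.softmax_cross_entropy(logits, nn.one_hot(ytr[sel], n_classes))
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            grads = ad.grad(loss, [model.params[k] for k in names])
            opt.step({k: g for k, g in zip(names, grads)})
            ep_loss += loss.item() * len(sel)
            ep_hits += topk_accuracy(logits.data, ytr[sel], 1) * len(sel)
        val_loss, val_acc = evaluate(model, xval, yval)
        history.append({"epoch": epoch, "lr": lr,
                        "train_loss": ep_loss / len(ytr),
                        "train_acc": ep_hits / len(ytr),
                        "val_loss": val_loss, "val_acc": val_acc})
        if val_acc > best["val_acc"]:
            best = {"val_acc": val_acc, "params": model.clone_params(),
                    "bn_running": {k: {s: v.copy() for s, v in st.items()}
                                   for k, st in model.bn_running.items()}}
    if cfg.epochs and "bn_running" in best:
        model.bn_running = best["bn_running"]
    return best["params"], history


def pretrain_transfer_eval(model, x, y, subjects, train_subjects, test_subjects,
                           cfg: TrainConfig, val_fraction=0.3):
    """Train on one subject group, evaluate frozen on another.

    The training subjects' samples are split 70/30 (stratified) into train
    and validation; the returned pair is (validation accuracy within the
    training subjects, frozen test accuracy on the held-out subjects).
    """
    train_subjects, test_subjects = set(train_subjects), set(test_subjects)
    overlap = train_subjects & test_subjects
    if overlap:
        raise ValueError(f"subjects {sorted(overlap)} in both train and test")
    subjects = np.asarray(subjects, dtype=int)
    tr_mask = np.isin(subjects, sorted(train_subjects))
    te_mask = np.isin(subjects, sorted(test_subjects))
    xtr_all, ytr_all = x[tr_mask], np.asarray(y)[tr_mask]
    idx_tr, idx_val, _ = split_dataset(
        xtr_all, ytr_all, ratios=(1 - val_fraction, val_fraction, 0.0),
        seed=cfg.seed)
    params, _ = train_supervised(
        model, (xtr_all[idx_tr], ytr_all[idx_tr]),
        (xtr_all[idx_val], ytr_all[idx_val]), cfg)
    model.set_params(params)
    _, val_acc = evaluate(model, xtr_all[idx_val], ytr_all[idx_val])
    _, test_acc = evaluate(model, x[te_mask], np.asarray(y)[te_mask])
    return val_acc, test_acc
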