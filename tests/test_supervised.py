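"""Supervised training: stratified splits, schedule, checkpointing, and the
learnability of the synthetic profile."""

import numpy as np
import pytest

from emgmeta import (CSACNet, NetworkConfig, TrainConfig, evaluate,
                     split_dataset, train_supervised)
from emgmeta import autodiff as ad


def test_split_622_sizes_and_partition():
    y = np.repeat(np.arange(5), 20)           # 100 samples, 5 balanced classes
    tr, va, te = split_dataset(np.zeros((100, 1)), y, (0.6, 0.2, 0.2), seed=0)
    assert (len(tr), len(va), len(te)) == (60, 20, 20)
    allidx = np.concatenate([tr, va, te])
    assert np.array_equal(np.sort(allidx), np.arange(100))
    for pool in (tr, va, te):                 # stratification: every class present
        assert set(y[pool]) == set(range(5))


def test_split_deterministic_given_seed():
    y = np.repeat(np.arange(4), 10)
    a = split_dataset(np.zeros((40, 1)), y, seed=5)
    b = split_dataset(np.zeros((40, 1)), y, seed=5)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa, pb)


def test_split_small_class_rejected():
    y = np.array([0, 0, 0, 1, 1])             # class 1 has 2 < 3 samples
    with pytest.raises(ValueError):
        split_dataset(np.zeros((5, 1)), y, (0.6, 0.2, 0.2))


def test_split_bad_ratios_rejected():
    with pytest.raises(ValueError):
        split_dataset(np.zeros((10, 1)), np.zeros(10, dtype=int), (0.5, 0.2, 0.2))


def _toy_problem(rng, n_per_class=30, n_classes=3):
    """Linearly separable 4-channel images."""
    y = np.repeat(np.arange(n_classes), n_per_class)
    x = rng.normal(size=(len(y), 4, 12, 12)) * 0.3
    for c in range(n_classes):
        x[y == c, c % 4, :, :] += 1.5
    return x, y


def test_zero_epochs_returns_initial_parameters(rng):
    x, y = _toy_problem(rng)
    net = CSACNet(NetworkConfig(in_channels=4, n_classes=3, cells=((4, 4),),
                                reduction=2, head_pool=(2, 2)), seed=0)
    before = {k: v.data.copy() for k, v in net.params.items()}
    params, history = train_supervised(net, (x, y), (x, y),
                                       TrainConfig(epochs=0))
    assert history == []
    for k in params:
        assert np.array_equal(params[k].data, before[k])


def test_lr_schedule_drops_after_configured_epoch(rng):
    x, y = _toy_problem(rng, n_per_class=10)
    net = CSACNet(NetworkConfig(in_channels=4, n_classes=3, cells=((4, 4),),
                                reduction=2, head_pool=(2, 2)), seed=0)
    cfg = TrainConfig(epochs=4, lr_drop_epoch=2, lr=0.001, lr_after_drop=0.0001)
    _, history = train_supervised(net, (x, y), (x, y), cfg)
    assert [h["lr"] for h in history] == [0.001, 0.001, 0.0001, 0.0001]


def test_best_validation_checkpoint_returned(rng):
    x, y = _toy_problem(rng)
    idx = np.arange(len(y))
    rng.shuffle(idx)
    tr, va = idx[:60], idx[60:]
    net = CSACNet(NetworkConfig(in_channels=4, n_classes=3, cells=((4, 4),),
                                reduction=2, head_pool=(2, 2)), seed=0)
    params, history = train_supervised(net, (x[tr], y[tr]), (x[va], y[va]),
                                       TrainConfig(epochs=6, lr_drop_epoch=4))
    net.set_params(params)
    _, returned_val = evaluate(net, x[va], y[va])
    best_seen = max(h["val_acc"] for h in history)
    assert returned_val >= best_seen - 1e-9


def test_no_shift_control_transfer_matches_validation():
    """Without the sleeve rotation, frozen new-subject accuracy tracks
    within-subjects validation accuracy (mean gap under 5 points over two
    dataset realizations)."""
    from emgmeta.experiments import transfer_gap_experiment
    with ad.default_dtype(np.float32):
        gaps = [transfer_gap_experiment(s, test_shift=0)["gap"]
                for s in (1, 9)]
    assert abs(float(np.mean(gaps))) < 0.05


def test_shuffled_labels_overfit_without_generalizing(rng):
    """Overfitting control: with labels randomly shuffled, training accuracy
    rises well above chance while validation accuracy stays near it."""
    with ad.default_dtype(np.float32):
        x, y = _toy_problem(rng, n_per_class=20)
        y = rng.permutation(y)                      # destroy the signal
        idx = np.arange(len(y))
        rng.shuffle(idx)
        tr, va = idx[:45], idx[45:]
        net = CSACNet(NetworkConfig(in_channels=4, n_classes=3, cells=((4, 8),),
                                    reduction=2, head_pool=(2, 2)), seed=0)
        cfg = TrainConfig(epochs=30, lr_drop_epoch=25, lr=0.003, batch=16)
        _, history = train_supervised(net, (x[tr], y[tr]), (x[va], y[va]), cfg)
        assert history[-1]["train_acc"] > 0.6          # memorization
        assert max(h["val_acc"] for h in history) < 0.62  # no generalization


def test_easy_problem_learned_quickly(rng):
    """A linearly separable toy problem reaches >90% validation accuracy in
    a few epochs."""
    with ad.default_dtype(np.float32):
        x, y = _toy_problem(rng, n_per_class=40)
        idx = split_dataset(x, y, (0.6, 0.2, 0.2), seed=0)
        net = CSACNet(NetworkConfig(in_channels=4, n_classes=3, cells=((4, 8),),
                                    reduction=2, head_pool=(2, 2)), seed=0)
        cfg = TrainConfig(epochs=8, lr_drop_epoch=6, lr=0.003, batch=32)
        _, history = train_supervised(net, (x[idx[0]], y[idx[0]]),
                                      (x[idx[1]], y[idx[1]]), cfg)
        assert max(h["val_acc"] for h in history) > 0.9
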