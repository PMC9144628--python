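"""N-way K-shot episodic task construction.

A task draws N classes from a pool and 2K distinct samples per class, K for
the support set (adaptation) and K for the query set (evaluation). Support
and query share the same N classes but never share a sample; labels are
remapped to 0..N−1 within the task. Meta-train, meta-validation and
meta-test pools are built from disjoint subject sets, so meta-testing always
measures adaptation to subjects never seen in training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Pool", "Task", "sample_task", "task_stream", "topk_accuracy"]


class Pool:
    """Feature array with labels, subjects and stable sample identities."""

    def __init__(self, x, y, subjects=None, ids=None):
        self.x = np.asarray(x)
        self.y = np.asarray(y, dtype=int)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y lengths differ")
        n = self.y.shape[0]
        self.subjects = (np.zeros(n, dtype=int) if subjects is None
                         else np.asarray(subjects, dtype=int))
        self.ids = np.arange(n) if ids is None else np.asarray(ids)
        self.classes = np.unique(self.y)
        self._by_class = {c: np.flatnonzero(self.y == c) for c in self.classes}

    def __len__(self):
        return self.y.shape[0]

    @classmethod
    def from_samples(cls, samples, mode="stft", stft_cfg=None):
        from .features import STFTConfig, featurize
        x, y, subj = featurize(samples, mode, stft_cfg or STFTConfig())
        return cls(x, y, subjects=subj)


@dataclass
class Task:
    """One few-shot episode: N·K support and N·K query samples."""

    support_x: np.ndarray
    support_y: np.ndarray   # remapped to 0..N-1
    query_x: np.ndarray
    query_y: np.ndarray
    class_map: np.ndarray   # position i holds the global class of task label i
    support_ids: np.ndarray
    query_ids: np.ndarray

    @property
    def n_way(self):
        return len(self.class_map)

    def to_global(self, task_labels):
        """Invert the label remapping back to pool classes."""
        return self.class_map[np.asarray(task_labels, dtype=int)]

    def manifest(self):
        """JSON-serializable record of the task's sample identities, for
        debugging and reproducibility audits."""
        return {
            "classes": [int(c) for c in self.class_map],
            "support_ids": [int(i) for i in self.support_ids],
            "query_ids": [int(i) for i in self.query_ids],
        }


def sample_task(pool: Pool, n_way=5, k_shot=1, rng=None, within_subject=False) -> Task:
    """Draw one N-way K-shot task: N classes, then 2K distinct samples each,
    split half support / half query.

    With ``within_subject=True`` a task is one subject's classification
    problem: a subject is drawn first and all 2K·N samples come from that
    subject. This mirrors the target setting — adapting to a single new
    user — and gives meta-training tasks whose labels are internally
    consistent under strong subject shift. The default draws from the whole
    pool regardless of subject.
    """
    rng = np.random.default_rng(rng)
    if within_subject:
        subject = rng.choice(np.unique(pool.subjects))
        sel = np.flatnonzero(pool.subjects == subject)
        sub = Pool(pool.x[sel], pool.y[sel], pool.subjects[sel], pool.ids[sel])
        return sample_task(sub, n_way, k_shot, rng, within_subject=False)
    if len(pool.classes) < n_way:
        raise ValueError(f"pool has {len(pool.classes)} classes, task needs {n_way}")
    classes = rng.choice(pool.classes, size=n_way, replace=False)
    sup_idx, qry_idx = [], []
    for c in classes:
        members = pool._by_class[c]
        if len(members) < 2 * k_shot:
            raise ValueError(
                f"class {c} has {len(members)} samples, needs {2 * k_shot}")
        chosen = rng.choice(members, size=2 * k_shot, replace=False)
        sup_idx.extend(chosen[:k_shot])
        qry_idx.extend(chosen[k_shot:])
    sup_idx = np.array(sup_idx)
    qry_idx = np.array(qry_idx)
    remap = {c: i for i, c in enumerate(classes)}
    return Task(
        support_x=pool.x[sup_idx],
        support_y=np.array([remap[c] for c in pool.y[sup_idx]]),
        query_x=pool.x[qry_idx],
        query_y=np.array([remap[c] for c in pool.y[qry_idx]]),
        class_map=np.asarray(classes),
        support_ids=pool.ids[sup_idx],
        query_ids=pool.ids[qry_idx],
    )


def task_stream(pool: Pool, n_tasks, n_way=5, k_shot=1, seed=0,
                within_subject=False):
    """A deterministic generator of ``n_tasks`` tasks for a given seed."""
    rng = np.random.default_rng(seed)
    for _ in range(int(n_tasks)):
        yield sample_task(pool, n_way, k_shot, rng, within_subject)


def topk_accuracy(scores, labels, k=1):
    """Fraction of samples whose true label is among the k top-scoring classes."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=int).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > scores.shape[1]:
        raise ValueError(f"k={k} exceeds class count {scores.shape[1]}")
    topk = np.argpartition(-scores, k - 1, axis=1)[:, :k]
    return float(np.mean(np.any(topk == labels[:, None], axis=1)))
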