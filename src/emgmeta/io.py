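"""Dataset serialization, CapgMyo ingestion and pipeline orchestration.

Synthetic (or any) recordings round-trip through a directory of NPZ bundles
plus a CSV manifest with columns file, subject, gesture, repetition, fs.
CapgMyo MAT files (v5 via scipy.io, v7.3 via h5py) are read through a
configurable field map because field names vary across the dataset's
releases. CapgMyo itself is an external download (http://zju-capg.org); this
module only ingests it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import STFTConfig
from .meta import MetaConfig
from .model import NetworkConfig
from .supervised import TrainConfig
from .synthetic import ConfigurationError, Recording, SynthConfig

__all__ = ["save_dataset", "load_dataset", "load_capgmyo", "RunConfig",
           "run_pipeline"]

MANIFEST = "manifest.csv"
CAPGMYO_CHANNELS = 128
CAPGMYO_GESTURES = {"a": 8, "b": 8, "c": 12}
DEFAULT_FIELD_MAP = {"signal": "data", "gesture": "gesture",
                     "subject": "subject", "repetition": "trial"}


def save_dataset(directory, recordings):
    """Write recordings as NPZ bundles plus a CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        name = f"rec_{i:05d}.npz"
        np.savez(directory / name, signal=rec.signal)
        rows.append({"file": name, "subject": rec.subject, "gesture": rec.gesture,
                     "repetition": rec.repetition, "fs": rec.fs})
    pd.DataFrame(rows).to_csv(directory / MANIFEST, index=False)
    return directory / MANIFEST


def load_dataset(directory):
    """Read a dataset written by :func:`save_dataset`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / MANIFEST)
    recordings = []
    for row in manifest.itertuples():
        with np.load(directory / row.file) as z:
            signal = z["signal"]
        recordings.append(Recording(signal, float(row.fs), int(row.gesture),
                                    int(row.subject), int(row.repetition)))
    return recordings


def _read_mat(path):
    try:
        from scipy.io import loadmat
        return {k: v for k, v in loadmat(path).items() if not k.startswith("__")}
    except NotImplementedError:
        import h5py
        out = {}
        with h5py.File(path, "r") as f:
            for k in f.keys():
                out[k] = np.array(f[k]).T  # MATLAB v7.3 stores column-major
        return out


def _scalar(value):
    return int(np.asarray(value).ravel()[0])


def load_capgmyo(directory, db="a", field_map=None, fs=1000.0):
    """Load a CapgMyo sub-database (DB-a/b/c) from its MAT files.

    Each MAT file holds one trial: a T×128 (or 128×T) signal array plus
    scalar subject/gesture/trial fields, named per ``field_map``. Validates
    the 128-channel geometry and the sub-database's gesture count (8 for
    DB-a/DB-b, 12 for DB-c).
    """
    if db not in CAPGMYO_GESTURES:
        raise ValueError("db must be one of 'a', 'b', 'c'")
    fmap = dict(DEFAULT_FIELD_MAP, **(field_map or {}))
    directory = Path(directory)
    paths = sorted(directory.glob("*.mat"))
    if not paths:
        raise FileNotFoundError(
            f"no .mat files in {directory}; expected CapgMyo DB-{db} trials "
            f"(external download from http://zju-capg.org)")
    recordings = []
    for path in paths:
        mat = _read_mat(path)
        missing = [v for v in fmap.values() if v not in mat]
        if missing:
            raise KeyError(f"{path.name}: missing fields {missing}; "
                           f"available: {sorted(mat)}; adjust field_map")
        sig = np.asarray(mat[fmap["signal"]], dtype=np.float64)
        if sig.ndim != 2 or CAPGMYO_CHANNELS not in sig.shape:
            raise ValueError(
                f"{path.name}: expected a {CAPGMYO_CHANNELS}-channel signal, "
                f"got shape {sig.shape}")
        if sig.shape[0] != CAPGMYO_CHANNELS:
            sig = sig.T
        recordings.append(Recording(
            sig, fs, _scalar(mat[fmap["gesture"]]), _scalar(mat[fmap["subject"]]),
            _scalar(mat[fmap["repetition"]])))
    n_gestures = len({r.gesture for r in recordings})
    expected = CAPGMYO_GESTURES[db]
    if n_gestures > expected:
        raise ValueError(f"DB-{db} should have {expected} gestures, "
                         f"found {n_gestures}")
    return recordings


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    synth: SynthConfig = field(default_factory=SynthConfig.small)
    stft: STFTConfig = field(default_factory=STFTConfig)
    network: NetworkConfig = None
    train: TrainConfig = field(default_factory=TrainConfig)
    meta: MetaConfig = field(default_factory=MetaConfig)
    mode: str = "stft"             # feature mode
    regime: str = "supervised"     # 'supervised' or 'meta'
    n_meta_batches: int = 300
    n_test_tasks: int = 200
    n_way: int = 5
    k_shot: int = 5
    train_subjects: tuple = ()
    val_subjects: tuple = ()
    test_subjects: tuple = ()
    capgmyo_dir: str = ""
    capgmyo_db: str = "a"
    out_dir: str = "runs/run"
    seed: int = 0

    def to_dict(self):
        from dataclasses import asdict
        d = asdict(self)
        d["network"] = None if self.network is None else json.loads(self.network.to_json())
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["synth"] = SynthConfig(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in d["synth"].items()})
        d["stft"] = STFTConfig(**d["stft"])
        if d.get("network"):
            d["network"] = NetworkConfig.from_json(json.dumps(d["network"]))
        d["train"] = TrainConfig(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in d["train"].items()})
        d["meta"] = MetaConfig(**d["meta"])
        for k in ("train_subjects", "val_subjects", "test_subjects"):
            d[k] = tuple(d.get(k, ()))
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path):
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig):
    """Execute synth → preprocess → featurize → train per the run config.

    Writes the resolved config, a metrics JSON and a model checkpoint under
    ``config.out_dir``; deterministic given the config's seeds.
    """
    from .episodes import Pool, task_stream
    from .features import featurize
    from .meta import meta_test, meta_train
    from .model import CSACNet
    from .preprocess import preprocess_recording
    from .supervised import evaluate, split_dataset, train_supervised
    from .synthetic import generate_dataset, make_fewshot_splits

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    if config.capgmyo_dir:
        if not Path(config.capgmyo_dir).exists():
            raise ConfigurationError(
                f"external data required: CapgMyo directory "
                f"{config.capgmyo_dir!r} does not exist (download from "
                f"http://zju-capg.org)")
        recordings = stage("load", load_capgmyo, config.capgmyo_dir,
                           config.capgmyo_db)
    else:
        recordings = stage("synth", generate_dataset, config.synth)

    samples = stage("preprocess", lambda rs: [preprocess_recording(r) for r in rs],
                    recordings)
    metrics = {"regime": config.regime, "mode": config.mode}

    if config.regime == "supervised":
        x, y, _ = stage("featurize", featurize, samples, config.mode, config.stft)
        net = CSACNet(config.network or NetworkConfig.small(
            x.shape[1], int(y.max()) + 1), seed=config.seed)
        idx = stage("split", split_dataset, x, y, config.train.split,
                    config.train.seed)
        params, history = stage(
            "train", train_supervised, net, (x[idx[0]], y[idx[0]]),
            (x[idx[1]], y[idx[1]]), config.train)
        net.set_params(params)
        pd.DataFrame(history).to_csv(out / "history.csv", index=False)
        _, metrics["val_acc"] = evaluate(net, x[idx[1]], y[idx[1]])
        if len(idx[2]):
            _, metrics["test_acc"] = evaluate(net, x[idx[2]], y[idx[2]])
    elif config.regime == "meta":
        pools = stage("split", make_fewshot_splits, samples,
                      config.train_subjects, config.val_subjects,
                      config.test_subjects)
        feat = [stage("featurize", featurize, p, config.mode, config.stft)
                for p in pools]
        train_pool = Pool(feat[0][0], feat[0][1], feat[0][2])
        test_pool = Pool(feat[2][0], feat[2][1], feat[2][2])
        net = CSACNet(config.network or NetworkConfig.small(
            train_pool.x.shape[1], config.n_way), seed=config.seed)
        log = stage("meta-train", meta_train, net,
                    task_stream(train_pool, config.meta.n_tasks, config.n_way,
                                config.k_shot, config.meta.seed),
                    config.meta, n_meta_batches=config.n_meta_batches)
        pd.DataFrame(log).to_csv(out / "history.csv", index=False)
        summary = stage("meta-test", meta_test, net,
                        task_stream(test_pool, config.n_test_tasks, config.n_way,
                                    config.k_shot, config.meta.seed + 1),
                        config.meta)
        summary.pop("results")
        metrics.update(summary)
    else:
        raise ConfigurationError(f"unknown regime {config.regime!r}")

    net.save(out / "model.npz")
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return metrics
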