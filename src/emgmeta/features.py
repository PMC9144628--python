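"""Input representations for the classifier.

Four representations of a preprocessed window are supported:

- ``stft``: per-channel magnitude of the short-time Fourier transform with a
  length-64 Hann taper and hop 29. Frames start at sample 0 with no centering
  or padding, so a 1000-sample channel yields floor((1000−64)/29)+1 = 33
  frames and 64/2+1 = 33 one-sided frequency bins — a 33×33 time-frequency
  image per channel, the primary model input;
- ``fft``: the one-sided magnitude spectrum of the whole window (501 bins at
  length 1000), treated as a single-channel image across electrodes;
- ``raw``: the window itself as a 1×L×C single-channel image;
- ``mav``: mean absolute value over a 200 ms window sliding by 25 ms, the
  classical sEMG amplitude feature (33 windows at 1 kHz and L=1000).

The spectrogram is plain magnitude (not power, not dB); ``log1p`` is
available as an option where compression helps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .preprocess import Sample

__all__ = ["STFTConfig", "FeatureTensor", "stft_spectrogram", "fft_spectrum",
           "raw_image", "mav_features", "featurize"]

MODES = ("stft", "fft", "raw", "mav")


@dataclass(frozen=True)
class STFTConfig:
    window_kind: str = "hann"
    window_len: int = 64
    hop: int = 29
    one_sided: bool = True
    log1p: bool = False

    def validate(self):
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if not (1 <= self.hop <= self.window_len):
            raise ValueError("hop must be in [1, window_len]")
        return self

    @property
    def n_freqs(self):
        return self.window_len // 2 + 1 if self.one_sided else self.window_len

    def n_frames(self, length):
        if length < self.window_len:
            raise ValueError(f"signal length {length} shorter than window "
                             f"{self.window_len}")
        return (length - self.window_len) // self.hop + 1


@dataclass
class FeatureTensor:
    """A model input with its representation tag.

    shapes: ``stft`` C×F×T (F=T=33 at defaults), ``fft`` C×F, ``raw`` 1×L×C,
    ``mav`` C×W.
    """

    values: np.ndarray
    mode: str
    gesture: int = -1
    subject: int = -1

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.values = np.asarray(self.values, dtype=np.float64)

    def as_model_input(self):
        """A C×H×W array ready for the network (adds the unit channel axis
        for the single-channel modes)."""
        if self.mode == "stft":
            return self.values
        if self.mode in ("fft", "mav"):
            return self.values[None, :, :]
        return self.values  # raw already 1×L×C


def stft_spectrogram(sample: Sample, cfg: STFTConfig = STFTConfig()) -> FeatureTensor:
    """Per-channel magnitude spectrogram, frames fully supported (no padding)."""
    cfg.validate()
    x = sample.window
    n_frames = cfg.n_frames(x.shape[1])
    win = get_window(cfg.window_kind, cfg.window_len, fftbins=False)
    starts = np.arange(n_frames) * cfg.hop
    frames = np.stack([x[:, s:s + cfg.window_len] for s in starts], axis=1)  # C,T,len
    spec = np.fft.rfft(frames * win, axis=2) if cfg.one_sided \
        else np.fft.fft(frames * win, axis=2)
    mag = np.abs(spec).transpose(0, 2, 1)  # C × freq × frames
    if cfg.log1p:
        mag = np.log1p(mag)
    return FeatureTensor(mag, "stft", sample.gesture, sample.subject)


def fft_spectrum(sample: Sample) -> FeatureTensor:
    """One-sided magnitude spectrum per channel (bin k ↔ k·fs/L Hz)."""
    mag = np.abs(np.fft.rfft(sample.window, axis=1))
    return FeatureTensor(mag, "fft", sample.gesture, sample.subject)


def raw_image(sample: Sample) -> FeatureTensor:
    """The time-domain window as a single-channel L×C image."""
    return FeatureTensor(sample.window.T[None, :, :], "raw",
                         sample.gesture, sample.subject)


def mav_features(sample: Sample, window_ms=200.0, step_ms=25.0) -> FeatureTensor:
    """Mean absolute value over sliding windows, per channel."""
    n = int(round(window_ms * sample.fs / 1000.0))
    s = int(round(step_ms * sample.fs / 1000.0))
    length = sample.window.shape[1]
    if n > length:
        raise ValueError(f"MAV window ({n} samples) longer than sample ({length})")
    n_win = (length - n) // s + 1
    starts = np.arange(n_win) * s
    out = np.stack([np.mean(np.abs(sample.window[:, t:t + n]), axis=1)
                    for t in starts], axis=1)
    return FeatureTensor(out, "mav", sample.gesture, sample.subject)


def featurize(samples, mode="stft", stft_cfg: STFTConfig = STFTConfig()):
    """Stack features for a list of samples into (X, gestures, subjects)."""
    fns = {"stft": lambda s: stft_spectrogram(s, stft_cfg), "fft": fft_spectrum,
           "raw": raw_image, "mav": mav_features}
    feats = [fns[mode](s) for s in samples]
    x = np.stack([f.as_model_input() for f in feats])
    y = np.array([s.gesture for s in samples], dtype=int)
    subj = np.array([s.subject for s in samples], dtype=int)
    return x, y, subj
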