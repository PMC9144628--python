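"""Raw-recording preprocessing: powerline notch, middle window, z-scoring.

The pipeline is filter → extract the middle one-second window → normalize,
yielding a fixed 1000-sample multichannel window per trial (at 1 kHz), the
unit of classification for every downstream feature and model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import Recording

__all__ = ["Sample", "bandstop_filter", "extract_middle_window", "normalize",
           "preprocess_recording"]


@dataclass
class Sample:
    """A preprocessed fixed-length multichannel window."""

    window: np.ndarray   # channels × length
    fs: float
    gesture: int
    subject: int

    def __post_init__(self):
        self.window = np.asarray(self.window, dtype=np.float64)
        if self.window.ndim != 2:
            raise ValueError("window must be channels × length")


def bandstop_filter(recording: Recording, band=(45.0, 55.0), order=2) -> Recording:
    """Zero-phase Butterworth band-stop, the 50 Hz powerline notch.

    Forward-backward filtering doubles the attenuation and removes phase
    distortion; the windows cut from the result feed time-frequency features
    where phase shifts would smear energy across frames.
    """
    lo, hi = band
    if not (0.0 < lo < hi < recording.fs / 2):
        raise ValueError(f"band {band} must lie inside (0, {recording.fs / 2}) Hz")
    sos = sps.butter(order, band, btype="bandstop", fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)
    return Recording(filtered, recording.fs, recording.gesture,
                     recording.subject, recording.repetition)


def extract_middle_window(recording: Recording, duration=1.0) -> Sample:
    """The centered contiguous block of ``duration`` seconds per channel.

    Start index is floor((T − L)/2): ties between two possible centres break
    toward the earlier sample.
    """
    t = recording.signal.shape[1]
    length = int(round(duration * recording.fs))
    if t < length:
        raise ValueError(f"recording has {t} samples, window needs {length}")
    start = (t - length) // 2
    return Sample(recording.signal[:, start:start + length].copy(),
                  recording.fs, recording.gesture, recording.subject)


def normalize(sample: Sample) -> Sample:
    """Per-channel z-score; constant channels map to zeros (SD floor 1e-12)."""
    if not np.all(np.isfinite(sample.window)):
        raise ValueError("sample contains non-finite values")
    mean = sample.window.mean(axis=1, keepdims=True)
    sd = sample.window.std(axis=1, keepdims=True)
    window = (sample.window - mean) / np.maximum(sd, 1e-12)
    return Sample(window, sample.fs, sample.gesture, sample.subject)


def preprocess_recording(recording: Recording, band=(45.0, 55.0), order=2,
                         duration=1.0) -> Sample:
    """Full pipeline: band-stop filter, middle window, per-channel z-score."""
    return normalize(extract_middle_window(bandstop_filter(recording, band, order),
                                           duration))
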