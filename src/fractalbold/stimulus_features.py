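"""Movie stimulus feature time series: brightness, audio RMS, audio ZCR.

The three features summarize the visual and auditory temporal dynamics of
a movie stimulus so their fractal structure can be compared with that of
the evoked BOLD signal.  Brightness is the per-frame mean luminance
(Rec. 601 weights for color frames); RMS and zero-crossing rate are
computed over non-overlapping-or-hopping audio windows, yielding uniformly
sampled series that feed :func:`fractalbold.spectral_hurst.estimate_hurst`.
"""

from __future__ import annotations

import numpy as np

from .containers import AudioTrack, FrameStack, ScalingFit, UniformTimeSeries
from . import spectral_hurst

__all__ = ["brightness_series", "rms_series", "zcr_series", "feature_hurst",
           "REC601_WEIGHTS"]

#: Rec. 601 luma weights for RGB -> luminance conversion.
REC601_WEIGHTS = np.array([0.299, 0.587, 0.114])

MIN_FRAMES = 64
MIN_WINDOWS = 64


def brightness_series(stack: FrameStack) -> UniformTimeSeries:
    """Per-frame mean luminance, sampled at the frame rate."""
    frames = stack.frames
    if frames.shape[0] < MIN_FRAMES:
        raise ValueError(f"need at least {MIN_FRAMES} frames")
    if frames.ndim == 4:
        frames = frames @ REC601_WEIGHTS
    values = frames.mean(axis=(1, 2))
    return UniformTimeSeries(values, sampling_interval=1.0 / stack.frame_rate)


def _window_starts(n_samples: int, window: float, hop: float,
                   sample_rate: float):
    if hop <= 0 or window < hop:
        raise ValueError("need window >= hop > 0")
    win = int(round(window * sample_rate))
    hop_n = int(round(hop * sample_rate))
    if win < 1 or hop_n < 1:
        raise ValueError("window and hop must span at least one sample")
    if win > n_samples:
        raise ValueError("window longer than the track")
    n_windows = (n_samples - win) // hop_n + 1
    if n_windows < MIN_WINDOWS:
        raise ValueError(f"need at least {MIN_WINDOWS} windows, got {n_windows}")
    return win, hop_n, n_windows


def rms_series(track: AudioTrack, window: float = 1.0,
               hop: float = 1.0) -> UniformTimeSeries:
    """Root-mean-square amplitude per window; sampling interval = hop."""
    x = track.samples
    win, hop_n, n_windows = _window_starts(x.size, window, hop,
                                           track.sample_rate)
    starts = np.arange(n_windows) * hop_n
    idx = starts[:, None] + np.arange(win)[None, :]
    values = np.sqrt(np.mean(x[idx] ** 2, axis=1))
    return UniformTimeSeries(values, sampling_interval=hop)


def zcr_series(track: AudioTrack, window: float = 1.0,
               hop: float = 1.0) -> UniformTimeSeries:
    """Zero-crossing rate per window, in [0, 1]; sampling interval = hop.

    A crossing is a strict sign change between adjacent samples; exact
    zeros count as positive (touching zero is not a crossing).
    """
    x = track.samples
    win, hop_n, n_windows = _window_starts(x.size, window, hop,
                                           track.sample_rate)
    signs = x >= 0
    starts = np.arange(n_windows) * hop_n
    idx = starts[:, None] + np.arange(win)[None, :]
    s = signs[idx]
    crossings = (s[:, 1:] != s[:, :-1]).sum(axis=1)
    values = crossings / (win - 1)
    return UniformTimeSeries(values, sampling_interval=hop)


def feature_hurst(series: UniformTimeSeries, **params) -> ScalingFit:
    """Extended-Hurst fit of a stimulus feature series (Welch defaults)."""
    return spectral_hurst.estimate_hurst(series, **params)
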