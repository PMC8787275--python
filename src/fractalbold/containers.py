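"""Core data containers shared across the analysis modules.

The containers are thin, validated wrappers around numpy arrays and pandas
tables.  They carry the physical metadata (sampling interval, voxel size,
repetition time) that the estimators need, and nothing else: file I/O lives
in :mod:`fractalbold.io`, statistics in the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "UniformTimeSeries",
    "PowerSpectrum",
    "ScalingFit",
    "ClassicalHurst",
    "Volume4D",
    "LabelAtlas",
    "VoxelMap",
    "MotionTrace",
    "FrameStack",
    "AudioTrack",
    "PairedComparison",
    "CorrelationResult",
    "ICCEstimate",
    "ICCDifference",
    "MIN_SERIES_LENGTH",
]

#: Minimum number of samples for which spectral estimation is supported.
MIN_SERIES_LENGTH = 64


@dataclass(frozen=True)
class UniformTimeSeries:
    """Real-valued samples at a fixed sampling interval.

    Parameters
    ----------
    values : array-like
        The samples, arbitrary units.
    sampling_interval : float
        Time between consecutive samples, in seconds (the fMRI TR for
        voxel series).
    """

    values: np.ndarray
    sampling_interval: float

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("time series must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            raise ValueError("time series contains non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def nyquist(self) -> float:
        return 0.5 / self.sampling_interval


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density on a strictly increasing grid."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and power must be 1-D and equal length")
        if f.size and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be nonnegative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class ScalingFit:
    """Log-log power-law fit of a spectrum.

    ``beta`` is the spectral index (negative slope of log10 power against
    log10 frequency), ``hurst_extended`` the class-spanning Hurst exponent
    H' = (beta + 1) / 2, and ``signal_class`` either ``"fGn"`` (beta < 1,
    stationary) or ``"fBm"`` (beta >= 1, nonstationary).
    """

    beta: float
    intercept: float
    hurst_extended: float
    signal_class: str
    fit_band: tuple
    n_freq_bins: int
    r_squared: float

    def __post_init__(self):
        if self.signal_class not in ("fGn", "fBm"):
            raise ValueError("signal_class must be 'fGn' or 'fBm'")
        expected = (self.beta + 1.0) / 2.0
        if not np.isclose(self.hurst_extended, expected, rtol=0, atol=1e-12):
            raise ValueError("hurst_extended must equal (beta + 1) / 2")


@dataclass(frozen=True)
class ClassicalHurst:
    """Classical (class-conditional) Hurst exponent, in (0, 1) for both classes."""

    hurst: float
    signal_class: str


@dataclass
class Volume4D:
    """A 4-D fMRI volume: spatial grid x time, with voxel size and TR."""

    data: np.ndarray
    voxel_size: tuple
    tr: float
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("Volume4D data must have shape (x, y, z, t)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive extents (mm)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            aff = np.diag(list(self.voxel_size) + [1.0])
            self.affine = aff

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class LabelAtlas:
    """Integer region labels on a voxel grid; 0 is background.

    ``legend`` maps label -> region name.  The default legend follows the
    gray-matter + seven-network parcellation used throughout the package.
    """

    labels: np.ndarray
    legend: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D integer grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        if self.legend:
            missing = present - set(self.legend)
            if missing:
                raise ValueError(f"legend does not cover labels {sorted(missing)}")

    @property
    def grid_shape(self) -> tuple:
        return self.labels.shape

    def region_labels(self) -> list:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


@dataclass
class VoxelMap:
    """One scalar per voxel (e.g. an H' or ALFF map); NaN marks undefined voxels."""

    data: np.ndarray
    kind: str = "hurst"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VoxelMap data must be 3-D")


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-body motion parameters and the derived framewise displacement.

    ``params`` is (frames, 6): translations in mm then rotations in radians.
    ``fd`` has one entry per frame transition (length frames - 1), in mm.
    """

    params: np.ndarray
    fd: np.ndarray
    mean_fd: float

    def __post_init__(self):
        p = np.asarray(self.params, dtype=float)
        fd = np.asarray(self.fd, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError("motion parameters must have six columns")
        if fd.shape != (p.shape[0] - 1,):
            raise ValueError("fd must have one value per frame transition")
        if np.any(fd < 0):
            raise ValueError("framewise displacement must be nonnegative")
        if not np.isclose(self.mean_fd, fd.mean()):
            raise ValueError("mean_fd must equal mean(fd)")
        object.__setattr__(self, "params", p)
        object.__setattr__(self, "fd", fd)


@dataclass(frozen=True)
class FrameStack:
    """Time-ordered video frames (2-D grayscale or 3-channel) at a fixed rate."""

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self):
        fr = np.asarray(self.frames, dtype=float)
        if fr.ndim not in (3, 4):
            raise ValueError("frames must be (t, h, w) or (t, h, w, 3)")
        if fr.ndim == 4 and fr.shape[-1] != 3:
            raise ValueError("color frames must have three channels")
        if fr.shape[0] == 0 or fr.shape[1] == 0 or fr.shape[2] == 0:
            raise ValueError("empty frame stack")
        if not np.all(np.isfinite(fr)):
            raise ValueError("frames contain non-finite pixels")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "frames", fr)


@dataclass(frozen=True)
class AudioTrack:
    """A mono waveform with its sample rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1:
            raise ValueError("audio must be a 1-D waveform")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class PairedComparison:
    """Paired two-sided t-test result for one region (convention: movie - rest)."""

    region: str
    mean_difference: float
    t_statistic: float
    p_raw: float
    p_adjusted: float
    ci95: tuple
    effect_size_d: float
    n: int

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.mean_difference <= hi):
            raise ValueError("confidence interval must bracket the mean difference")
        if self.p_adjusted + 1e-12 < self.p_raw:
            raise ValueError("adjusted p cannot be smaller than raw p")


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple
    r: float
    p: float
    n: int

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r out of range")


@dataclass(frozen=True)
class ICCEstimate:
    """ICC(2,1) point estimate with bootstrap percentile CI and the
    conventional qualitative band (poor / fair / good / excellent)."""

    icc: float
    ci95: tuple
    n_boot: int
    interpretation: str


@dataclass(frozen=True)
class ICCDifference:
    icc_a: float
    icc_b: float
    difference: float
    ci95: tuple
    significant: bool
    n_boot: int
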