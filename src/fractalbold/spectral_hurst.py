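"""Spectral-index (beta) and Hurst-exponent estimation from the PSD.

The estimator treats a series as a realization of a power-law process,
|A(f)|^2 = c * f**(-beta).  The power spectral density is estimated with
Welch's method (eight Hann-tapered segments at 50% overlap by default) and
beta is the negative slope of an ordinary least-squares line fit to
log10(power) against log10(frequency) over a restricted band (above
0.01 Hz by default, up to Nyquist).

Two Hurst conventions are provided:

* the *extended* exponent H' = (beta + 1) / 2, which spans (0, 2) and
  encodes the signal class — H' < 1 for fractional Gaussian noise (fGn,
  stationary, beta < 1) and H' > 1 for fractional Brownian motion (fBm,
  nonstationary, beta > 1);
* the *classical* class-conditional exponent in (0, 1):
  H = (beta + 1) / 2 for fGn and H = (beta - 1) / 2 for fBm.  Two processes
  of different class sharing a classical H have betas differing by exactly 2,
  which is why the extended convention is preferred for reporting.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
from scipy import signal as sps

from .containers import (
    MIN_SERIES_LENGTH,
    ClassicalHurst,
    LabelAtlas,
    PowerSpectrum,
    ScalingFit,
    UniformTimeSeries,
    Volume4D,
    VoxelMap,
)

__all__ = [
    "welch_psd",
    "fit_scaling",
    "estimate_hurst",
    "classical_hurst",
    "classical_to_beta",
    "voxelwise_hurst",
    "segment_length",
]

logger = logging.getLogger(__name__)

DEFAULT_F_MIN = 0.01  # Hz; power-law scaling holds above this in BOLD data
DEFAULT_N_WINDOWS = 8
DEFAULT_OVERLAP = 0.5
MIN_SEGMENT_LENGTH = 32
MIN_FIT_BINS = 4


def segment_length(n_samples: int, n_windows: int = DEFAULT_N_WINDOWS,
                   overlap_fraction: float = DEFAULT_OVERLAP) -> int:
    """Welch segment length for ``n_windows`` segments at the given overlap.

    Solves N = L + (n_windows - 1) * L * (1 - overlap) for L and floors,
    e.g. 900 samples with 8 windows at 50% overlap gives L = 200.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    denom = 1.0 + (n_windows - 1) * (1.0 - overlap_fraction)
    return int(n_samples / denom)


def _noverlap(nperseg: int, overlap_fraction: float) -> int:
    """Overlap in samples such that the segment step is floor(L*(1-ov)):
    guarantees the requested window count fits for odd segment lengths."""
    return nperseg - int(nperseg * (1.0 - overlap_fraction))


def welch_psd(series: UniformTimeSeries, n_windows: int = DEFAULT_N_WINDOWS,
              overlap_fraction: float = DEFAULT_OVERLAP) -> PowerSpectrum:
    """One-sided Welch PSD with Hann taper and per-segment mean removal.

    The zero-frequency bin is excluded from the returned spectrum: under a
    power law the DC power is undefined, and the signals are treated as
    zero-mean.

    Raises
    ------
    ValueError
        If the series is too short for the requested segmentation, or is
        constant (zero power everywhere).
    """
    x = series.values
    if x.size < MIN_SERIES_LENGTH:
        raise ValueError(f"need at least {MIN_SERIES_LENGTH} samples, got {x.size}")
    nperseg = segment_length(x.size, n_windows, overlap_fraction)
    if nperseg < MIN_SEGMENT_LENGTH:
        raise ValueError(
            f"series of {x.size} samples yields segment length {nperseg} < "
            f"{MIN_SEGMENT_LENGTH}; use fewer windows or a longer series")
    if np.ptp(x) == 0:
        raise ValueError("constant series has zero spectral power; "
                         "the spectral index is undefined")
    fs = 1.0 / series.sampling_interval
    freqs, power = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=_noverlap(nperseg, overlap_fraction),
        detrend="constant", scaling="density")
    return PowerSpectrum(freqs[1:], power[1:])  # drop the DC bin


def fit_scaling(spectrum: PowerSpectrum, f_min: float = DEFAULT_F_MIN,
                f_max: Optional[float] = None) -> ScalingFit:
    """OLS fit of log10(power) on log10(frequency) over (f_min, f_max].

    ``beta`` is the negative slope; the lower bound is strict (frequencies
    strictly above ``f_min`` enter the fit) and the upper bound defaults to
    the highest available frequency (Nyquist for a Welch spectrum).
    Nonpositive-power bins inside the band are excluded with a logged count.

    Raises
    ------
    ValueError
        If fewer than four positive-power bins remain in the band.
    """
    f = spectrum.frequencies
    p = spectrum.power
    if f_max is None:
        f_max = float(f[-1]) if f.size else 0.0
    if f_max <= f_min:
        raise ValueError("f_max must exceed f_min")
    in_band = (f > f_min) & (f <= f_max)
    usable = in_band & (p > 0)
    n_dropped = int(in_band.sum() - usable.sum())
    if n_dropped:
        logger.warning("excluded %d nonpositive-power bins from the scaling fit",
                       n_dropped)
    if usable.sum() < MIN_FIT_BINS:
        raise ValueError(
            f"only {int(usable.sum())} positive-power bins in "
            f"({f_min}, {f_max}]; need at least {MIN_FIT_BINS}")
    logf = np.log10(f[usable])
    logp = np.log10(p[usable])
    slope, intercept = np.polyfit(logf, logp, 1)
    resid = logp - (slope * logf + intercept)
    ss_tot = np.sum((logp - logp.mean()) ** 2)
    r_squared = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    beta = -float(slope)
    return ScalingFit(
        beta=beta,
        intercept=float(intercept),
        hurst_extended=(beta + 1.0) / 2.0,
        signal_class="fGn" if beta < 1.0 else "fBm",
        fit_band=(float(f_min), float(f_max)),
        n_freq_bins=int(usable.sum()),
        r_squared=float(r_squared),
    )


def estimate_hurst(series: UniformTimeSeries, f_min: float = DEFAULT_F_MIN,
                   f_max: Optional[float] = None,
                   n_windows: int = DEFAULT_N_WINDOWS,
                   overlap_fraction: float = DEFAULT_OVERLAP) -> ScalingFit:
    """Welch PSD followed by the log-log scaling fit, with the defaults
    used throughout the pipeline (8 windows, 50% overlap, fit above 0.01 Hz)."""
    spectrum = welch_psd(series, n_windows=n_windows,
                         overlap_fraction=overlap_fraction)
    return fit_scaling(spectrum, f_min=f_min, f_max=f_max)


def classical_hurst(beta: float) -> ClassicalHurst:
    """Class-conditional classical Hurst exponent in (0, 1).

    H = (beta + 1)/2 for fGn (beta < 1) and H = (beta - 1)/2 for fBm
    (beta >= 1).  The beta = 1 boundary is assigned to fBm, consistent with
    the rest of the package.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if beta < 1.0:
        return ClassicalHurst(hurst=(beta + 1.0) / 2.0, signal_class="fGn")
    return ClassicalHurst(hurst=(beta - 1.0) / 2.0, signal_class="fBm")


def classical_to_beta(hurst: float, signal_class: str) -> float:
    """Invert the classical conversion: beta = 2H - 1 (fGn) or 2H + 1 (fBm)."""
    if signal_class == "fGn":
        return 2.0 * hurst - 1.0
    if signal_class == "fBm":
        return 2.0 * hurst + 1.0
    raise ValueError("signal_class must be 'fGn' or 'fBm'")


def _in_mask(mask: Union[LabelAtlas, np.ndarray]) -> np.ndarray:
    if isinstance(mask, LabelAtlas):
        return mask.labels > 0
    m = np.asarray(mask)
    if m.dtype == bool:
        return m
    return m > 0


def voxelwise_hurst(volume: Volume4D, mask: Union[LabelAtlas, np.ndarray],
                    f_min: float = DEFAULT_F_MIN, f_max: Optional[float] = None,
                    n_windows: int = DEFAULT_N_WINDOWS,
                    overlap_fraction: float = DEFAULT_OVERLAP) -> VoxelMap:
    """Extended-Hurst map over all in-mask voxels.

    Out-of-mask voxels are NaN; voxels whose fit fails (constant series or
    too few positive bins) are NaN with a logged count.  The result does not
    depend on the order in which voxels are processed.

    The in-mask voxel series are processed as one batch: a single vectorized
    Welch transform followed by a shared-design-matrix least-squares solve,
    with a per-voxel fallback for voxels containing zero-power bins.
    """
    inmask = _in_mask(mask)
    if inmask.shape != volume.grid_shape:
        raise ValueError("mask grid does not match volume grid")
    if not inmask.any():
        raise ValueError("empty mask")

    x = volume.data[inmask].astype(float)  # (n_voxels, n_frames)
    n = x.shape[1]
    if n < MIN_SERIES_LENGTH:
        raise ValueError(f"need at least {MIN_SERIES_LENGTH} frames, got {n}")
    nperseg = segment_length(n, n_windows, overlap_fraction)
    if nperseg < MIN_SEGMENT_LENGTH:
        raise ValueError("too few frames for the requested segmentation")
    fs = 1.0 / volume.tr
    freqs, power = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=_noverlap(nperseg, overlap_fraction),
        detrend="constant", scaling="density", axis=-1)
    freqs, power = freqs[1:], power[:, 1:]
    if f_max is None:
        f_max = float(freqs[-1])
    band = (freqs > f_min) & (freqs <= f_max)
    if band.sum() < MIN_FIT_BINS:
        raise ValueError("too few frequency bins in the fitting band")

    pb = power[:, band]
    logf = np.log10(freqs[band])
    design = np.column_stack([logf, np.ones_like(logf)])
    hurst = np.full(x.shape[0], np.nan)

    clean = np.all(pb > 0, axis=1)
    if clean.any():
        coef, *_ = np.linalg.lstsq(design, np.log10(pb[clean]).T, rcond=None)
        hurst[clean] = (-coef[0] + 1.0) / 2.0

    n_failed = 0
    for i in np.flatnonzero(~clean):
        try:
            spec = PowerSpectrum(freqs, power[i])
            hurst[i] = fit_scaling(spec, f_min=f_min, f_max=f_max).hurst_extended
        except ValueError:
            n_failed += 1
    if n_failed:
        logger.warning("%d voxels had undefined spectral slopes (set to NaN)",
                       n_failed)

    out = np.full(volume.grid_shape, np.nan)
    out[inmask] = hurst
    return VoxelMap(out, kind="hurst")
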