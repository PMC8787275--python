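"""Companion voxelwise BOLD measures: ALFF, temporal SD, Gaussian smoothing.

ALFF (amplitude of low-frequency fluctuations) is the sum of the amplitude
spectrum of a voxel series over the 0.01-0.08 Hz band, computed from the
full-length periodogram (no Welch averaging) — the band-limited amplitude
convention of AFNI's resting-state tools.  "Bandpass filtering" is realized
as frequency-bin selection, which is equivalent for a quantity defined bin
by bin.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .containers import (
    MIN_SERIES_LENGTH,
    LabelAtlas,
    UniformTimeSeries,
    Volume4D,
    VoxelMap,
)

__all__ = ["smooth_gaussian", "alff", "temporal_sd", "alff_map", "sd_map",
           "DEFAULT_ALFF_BAND", "FWHM_TO_SIGMA"]

DEFAULT_ALFF_BAND = (0.01, 0.08)  # Hz
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_gaussian(volume: Volume4D, fwhm: float = 5.0) -> Volume4D:
    """Per-frame 3-D Gaussian smoothing with the kernel width in mm.

    Sigma per axis is fwhm * FWHM_TO_SIGMA divided by that axis' voxel size,
    so anisotropic grids smooth isotropically in physical space.  Edges use
    reflect padding (map edges feed ROI means, so mass is kept in-volume).
    ``fwhm=0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm == 0:
        return Volume4D(volume.data.copy(), volume.voxel_size, volume.tr,
                        None if volume.affine is None else volume.affine.copy())
    sigma_vox = [fwhm * FWHM_TO_SIGMA / v for v in volume.voxel_size]
    smoothed = ndimage.gaussian_filter(
        volume.data.astype(float), sigma=sigma_vox + [0.0], mode="reflect")
    return Volume4D(smoothed, volume.voxel_size, volume.tr,
                    None if volume.affine is None else volume.affine.copy())


def alff(series: UniformTimeSeries,
         band: Tuple[float, float] = DEFAULT_ALFF_BAND) -> float:
    """Amplitude of low-frequency fluctuations of one series.

    Sum over full-length periodogram bins with band[0] <= f <= band[1]
    (DC excluded) of the square root of the periodogram power; linear in
    signal amplitude and nonnegative.
    """
    if len(series) < MIN_SERIES_LENGTH:
        raise ValueError(f"need at least {MIN_SERIES_LENGTH} samples")
    low, high = band
    nyquist = series.nyquist
    if not 0 < low < high <= nyquist + 1e-12:
        raise ValueError("band must satisfy 0 < low < high <= Nyquist")
    fs = 1.0 / series.sampling_interval
    freqs, power = sps.periodogram(series.values, fs=fs, window="boxcar",
                                   detrend="constant", scaling="density")
    in_band = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not in_band.any():
        raise ValueError("no frequency bins fall inside the band at this "
                         "series length")
    return float(np.sqrt(power[in_band]).sum())


def temporal_sd(series: UniformTimeSeries) -> float:
    """Sample standard deviation (n-1 denominator) of the series."""
    return float(np.std(series.values, ddof=1))


def _mask_array(volume: Volume4D, mask) -> np.ndarray:
    if mask is None:
        return np.ones(volume.grid_shape, dtype=bool)
    if isinstance(mask, LabelAtlas):
        m = mask.labels > 0
    else:
        m = np.asarray(mask) > 0 if np.asarray(mask).dtype != bool else np.asarray(mask)
    if m.shape != volume.grid_shape:
        raise ValueError("mask grid does not match volume grid")
    return m


def alff_map(volume: Volume4D, mask=None,
             band: Tuple[float, float] = DEFAULT_ALFF_BAND) -> VoxelMap:
    """Voxelwise ALFF; out-of-mask voxels are NaN."""
    m = _mask_array(volume, mask)
    x = volume.data[m].astype(float)
    fs = 1.0 / volume.tr
    freqs, power = sps.periodogram(x, fs=fs, window="boxcar",
                                   detrend="constant", scaling="density",
                                   axis=-1)
    in_band = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not in_band.any():
        raise ValueError("no frequency bins fall inside the band")
    out = np.full(volume.grid_shape, np.nan)
    out[m] = np.sqrt(power[:, in_band]).sum(axis=-1)
    return VoxelMap(out, kind="alff")


def sd_map(volume: Volume4D, mask=None) -> VoxelMap:
    """Voxelwise temporal standard deviation; out-of-mask voxels are NaN."""
    m = _mask_array(volume, mask)
    out = np.full(volume.grid_shape, np.nan)
    out[m] = volume.data[m].astype(float).std(axis=-1, ddof=1)
    return VoxelMap(out, kind="sd")
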