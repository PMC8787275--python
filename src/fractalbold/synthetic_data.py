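"""Synthetic inputs for every pipeline stage.

Nothing here models hemodynamics: the phantom encodes exactly the properties
the analysis measures — power-law voxel spectra with region- and
condition-specific spectral indices, between-subject and between-run
variability, white-noise admixture — so each downstream stage can be
verified end to end without any neuroimaging download.

Power-law series are produced by spectral synthesis: independent complex
Gaussian Fourier coefficients with amplitude proportional to f**(-beta/2),
Hermitian symmetry, inverse FFT, then rescaling to the requested variance.
The DC component is zero (power-law processes have no defined mean power at
f = 0).  An exact-covariance fGn synthesizer (Davies-Harte circulant
embedding) would be a drop-in alternative; spectral synthesis is used
because it matches the PSD-based estimator's model directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import (
    AudioTrack,
    FrameStack,
    LabelAtlas,
    UniformTimeSeries,
    Volume4D,
)

__all__ = [
    "PowerLawSpec",
    "PhantomDesign",
    "PhantomRun",
    "AudioSpec",
    "synthesize_power_law",
    "synthesize_phantom",
    "iter_phantom_runs",
    "phantom_atlas",
    "default_label_map",
    "default_phantom_design",
    "synthesize_motion",
    "synthesize_stimulus",
    "REGION_LEGEND",
    "DEFAULT_REST_HURST",
    "DEFAULT_CONDITION_EFFECT",
]

BETA_RANGE = (-1.0, 3.0)

#: Label legend: gray matter outside the seven networks, then the seven
#: canonical resting-state networks.
REGION_LEGEND = {
    1: "GM-other",
    2: "Vis",
    3: "SoM",
    4: "DAtt",
    5: "VAtt",
    6: "Lim",
    7: "FP",
    8: "DN",
}

#: Baseline (rest) extended-Hurst level per region, spanning the range
#: observed for gray matter and networks in 7T BOLD (~0.69-1.24).
DEFAULT_REST_HURST = {
    1: 0.95,   # GM-other
    2: 0.95,   # visual
    3: 0.90,   # somatomotor
    4: 0.92,   # dorsal attention
    5: 0.88,   # ventral attention
    6: 0.69,   # limbic
    7: 1.10,   # frontoparietal
    8: 1.24,   # default
}

#: Movie-minus-rest shift in extended H per region: positive in visual,
#: somatomotor and dorsal attention, negative in frontoparietal and default,
#: null in ventral attention and limbic; small positive in remaining GM.
DEFAULT_CONDITION_EFFECT = {
    1: 0.014,
    2: 0.096,
    3: 0.022,
    4: 0.026,
    5: 0.0,
    6: 0.0,
    7: -0.012,
    8: -0.010,
}

CONDITIONS = ("rest", "movie")


@dataclass(frozen=True)
class PowerLawSpec:
    """Specification of one power-law series realization."""

    beta_target: float
    n_samples: int
    sampling_interval: float = 1.0
    variance: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 64:
            raise ValueError("n_samples must be >= 64")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if not BETA_RANGE[0] <= self.beta_target <= BETA_RANGE[1]:
            raise ValueError(f"beta_target must lie in {BETA_RANGE}")


def _power_law_batch(n_series: int, n_samples: int, beta: float,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_series, n_samples) of unit-variance, zero-mean power-law noise."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0)  # d cancels in the slope
    amp = np.zeros(n_freq)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    coeffs = (rng.standard_normal((n_series, n_freq))
              + 1j * rng.standard_normal((n_series, n_freq)))
    coeffs[:, 0] = 0.0  # zero-mean signal: DC undefined under a power law
    if n_samples % 2 == 0:
        coeffs[:, -1] = coeffs[:, -1].real  # Nyquist bin must be real
    x = np.fft.irfft(coeffs * amp, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def synthesize_power_law(spec: PowerLawSpec) -> UniformTimeSeries:
    """One zero-mean series whose expected one-sided PSD follows
    f**(-beta_target); deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    x = _power_law_batch(1, spec.n_samples, spec.beta_target, rng)[0]
    x *= np.sqrt(spec.variance)
    return UniformTimeSeries(x, spec.sampling_interval)


def default_label_map(grid_shape: Tuple[int, int, int] = (16, 16, 8)) -> np.ndarray:
    """Default phantom parcellation: top and bottom slices are background,
    the interior is split into eight equal slabs along x (labels 1..8)."""
    nx, ny, nz = grid_shape
    if nx < 8 or nz < 3:
        raise ValueError("grid too small for the default eight-region parcellation")
    labels = np.zeros(grid_shape, dtype=np.int16)
    edges = np.linspace(0, nx, 9).astype(int)
    for region in range(1, 9):
        labels[edges[region - 1]:edges[region], :, 1:nz - 1] = region
    return labels


@dataclass
class PhantomDesign:
    """Phantom cohort layout: grid, parcellation, per-(region, condition)
    spectral indices and variability components.

    ``beta_by_region_condition`` maps (label, condition) -> beta.  Each voxel
    series is a mixture ``(1 - noise_fraction) * power_law + noise_fraction *
    white`` of unit-variance components.  Each subject draws one Gaussian
    beta offset per region (SD ``subject_jitter_sd``, shared across
    conditions and runs: the source of between-subject variance for ICC) and
    each run draws an independent offset (SD ``run_jitter_sd``: run-to-run
    state variability, the source of within-subject variance).
    """

    grid_shape: Tuple[int, int, int] = (16, 16, 8)
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_frames: int = 900
    tr: float = 1.0
    label_map: Optional[np.ndarray] = None
    beta_by_region_condition: Optional[Dict[Tuple[int, str], float]] = None
    noise_fraction: float = 0.05
    n_subjects: int = 24
    n_runs_per_condition: int = 4
    subject_jitter_sd: float = 0.05
    run_jitter_sd: float = 0.03
    background_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_runs_per_condition < 1:
            raise ValueError("n_runs_per_condition must be >= 1")
        if self.n_frames < 256:
            raise ValueError("n_frames must be >= 256")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must lie in [0, 1)")
        if self.label_map is None:
            self.label_map = default_label_map(self.grid_shape)
        else:
            self.label_map = np.asarray(self.label_map)
            if self.label_map.shape != tuple(self.grid_shape):
                raise ValueError("label_map shape does not match grid_shape")
        if self.beta_by_region_condition is None:
            self.beta_by_region_condition = {}
            for label, h_rest in DEFAULT_REST_HURST.items():
                self.beta_by_region_condition[(label, "rest")] = 2 * h_rest - 1
                self.beta_by_region_condition[(label, "movie")] = (
                    2 * (h_rest + DEFAULT_CONDITION_EFFECT[label]) - 1)
        self.regions = sorted(int(v) for v in np.unique(self.label_map) if v != 0)
        if not self.regions:
            raise ValueError("label map contains no labelled region")
        for label in self.regions:
            for cond in self.conditions:
                key = (label, cond)
                if key not in self.beta_by_region_condition:
                    raise ValueError(f"no beta specified for {key}")
                beta = self.beta_by_region_condition[key]
                if not BETA_RANGE[0] < beta < BETA_RANGE[1]:
                    raise ValueError(f"beta for {key} outside {BETA_RANGE}")

    @property
    def conditions(self) -> Tuple[str, ...]:
        if self.beta_by_region_condition:
            return tuple(sorted({c for (_, c) in self.beta_by_region_condition}))
        return CONDITIONS


def default_phantom_design(n_subjects: int = 24, seed: int = 0,
                           **overrides) -> PhantomDesign:
    return PhantomDesign(n_subjects=n_subjects, seed=seed, **overrides)


@dataclass(frozen=True)
class PhantomRun:
    """One synthesized subject x condition x run volume."""

    subject_id: str
    condition: str
    run: int
    volume: Volume4D


def phantom_atlas(design: PhantomDesign) -> LabelAtlas:
    legend = {label: REGION_LEGEND.get(label, f"region-{label}")
              for label in design.regions}
    return LabelAtlas(design.label_map.astype(np.int16), legend)


def _subject_betas(design: PhantomDesign, rng: np.random.Generator) -> np.ndarray:
    """Per-subject beta offsets, one per region (shared across conditions)."""
    return rng.normal(0.0, design.subject_jitter_sd,
                      size=(design.n_subjects, len(design.regions)))


def iter_phantom_runs(design: PhantomDesign) -> Iterator[PhantomRun]:
    """Yield runs one at a time (constant memory for large cohorts).

    Deterministic given ``design.seed``: each (subject, condition, run)
    stream is seeded independently, so iteration order does not matter.
    """
    root = np.random.SeedSequence(design.seed)
    subj_ss, runs_ss = root.spawn(2)
    jitter = _subject_betas(design, np.random.default_rng(subj_ss))
    voxels_per_region = {label: np.count_nonzero(design.label_map == label)
                         for label in design.regions}
    n_background = int(np.count_nonzero(design.label_map == 0))
    lo, hi = BETA_RANGE[0] + 0.05, BETA_RANGE[1] - 0.05

    n_cells = (len(design.conditions) * design.n_runs_per_condition)
    run_streams = runs_ss.spawn(design.n_subjects * n_cells)
    idx = 0
    for s in range(design.n_subjects):
        for condition in design.conditions:
            for run in range(1, design.n_runs_per_condition + 1):
                rng = np.random.default_rng(run_streams[idx])
                idx += 1
                data = np.empty(tuple(design.grid_shape) + (design.n_frames,),
                                dtype=np.float32)
                if n_background:
                    data[design.label_map == 0] = (
                        design.background_sd
                        * rng.standard_normal((n_background, design.n_frames)))
                for r_i, label in enumerate(design.regions):
                    beta = (design.beta_by_region_condition[(label, condition)]
                            + jitter[s, r_i]
                            + rng.normal(0.0, design.run_jitter_sd))
                    beta = float(np.clip(beta, lo, hi))
                    nv = voxels_per_region[label]
                    sig = _power_law_batch(nv, design.n_frames, beta, rng)
                    white = rng.standard_normal((nv, design.n_frames))
                    data[design.label_map == label] = (
                        (1.0 - design.noise_fraction) * sig
                        + design.noise_fraction * white)
                vol = Volume4D(data, voxel_size=design.voxel_size, tr=design.tr)
                yield PhantomRun(subject_id=f"sub-{s + 1:03d}",
                                 condition=condition, run=run, volume=vol)


def synthesize_phantom(design: PhantomDesign) -> Tuple[List[PhantomRun], LabelAtlas]:
    """Materialize the full phantom cohort.

    Returns every run plus the shared label atlas.  For large cohorts prefer
    :func:`iter_phantom_runs`, which yields runs lazily (a 16x16x8 x 900
    volume is ~7 MB; a 24-subject, 8-run cohort is ~1.4 GB if held at once).
    """
    return list(iter_phantom_runs(design)), phantom_atlas(design)


def synthesize_motion(n_frames: int, mean_fd_target: float = 0.12,
                      fd_beta: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Motion-parameter table whose framewise displacement has a prescribed
    mean and spectral index.

    A unit-variance power-law series g of index ``fd_beta`` is mapped to a
    nonnegative displacement trace fd = mean_fd_target * (1 + 0.25 g)
    (clipped at zero, then rescaled to the exact target mean; the affine map
    preserves the spectral slope and clipping is a < 1e-4 tail event).  The
    trace is then realized as sign-alternating x-translation increments, so
    recomputing FD from the returned parameters reproduces it exactly.

    Returns a DataFrame with columns trans_x, trans_y, trans_z (mm) and
    rot_x, rot_y, rot_z (radians), one row per frame.
    """
    if mean_fd_target <= 0:
        raise ValueError("mean_fd_target must be positive")
    if n_frames < 65:
        raise ValueError("need at least 65 frames (64 FD samples)")
    spec = PowerLawSpec(beta_target=fd_beta, n_samples=n_frames - 1, seed=seed)
    g = synthesize_power_law(spec).values
    fd = np.clip(mean_fd_target * (1.0 + 0.25 * g), 0.0, None)
    if fd.mean() == 0:
        raise ValueError("degenerate all-zero displacement trace")
    fd *= mean_fd_target / fd.mean()
    signs = np.where(np.arange(fd.size) % 2 == 0, 1.0, -1.0)
    params = np.zeros((n_frames, 6))
    params[1:, 0] = np.cumsum(signs * fd)
    return pd.DataFrame(
        params,
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"])


@dataclass(frozen=True)
class AudioSpec:
    """Audio synthesis parameters: sample rate, spectral index of the RMS
    envelope, and the envelope resolution in seconds."""

    sample_rate: float = 8000.0
    rms_beta: float = 0.68
    envelope_window: float = 1.0

    def __post_init__(self):
        if self.sample_rate <= 0 or self.envelope_window <= 0:
            raise ValueError("sample_rate and envelope_window must be positive")


def synthesize_stimulus(n_frames_video: int = 2048,
                        n_samples_audio: int = 512000,
                        brightness_beta: float = 1.588,
                        audio_spec: AudioSpec = AudioSpec(),
                        seed: int = 0,
                        frame_rate: float = 24.0,
                        frame_shape: Tuple[int, int] = (4, 4)
                        ) -> Tuple[FrameStack, AudioTrack]:
    """Movie-like stimulus: frames whose mean luminance follows a power law,
    and amplitude-modulated white-noise audio whose RMS envelope follows a
    power law.

    The video frames are spatially uniform — only the luminance *time
    course* carries structure, which is all the feature extraction measures.
    """
    if n_frames_video < 64:
        raise ValueError("need at least 64 video frames")
    root = np.random.SeedSequence(seed)
    vid_seed, aud_seed = [int(s.generate_state(1)[0] % (2 ** 31))
                          for s in root.spawn(2)]

    b = synthesize_power_law(PowerLawSpec(
        beta_target=brightness_beta, n_samples=n_frames_video,
        seed=vid_seed)).values
    luminance = np.clip(128.0 + 25.0 * b, 0.0, 255.0)
    frames = np.broadcast_to(
        luminance[:, None, None],
        (n_frames_video,) + tuple(frame_shape)).copy()

    win = int(round(audio_spec.envelope_window * audio_spec.sample_rate))
    n_windows = n_samples_audio // win
    if n_windows < 64:
        raise ValueError("audio too short for a 64-window RMS envelope")
    rng = np.random.default_rng(aud_seed)
    g = synthesize_power_law(PowerLawSpec(
        beta_target=audio_spec.rms_beta, n_samples=n_windows,
        seed=aud_seed)).values
    envelope = np.clip(1.0 + 0.3 * g, 0.05, None)
    carrier = rng.standard_normal(n_samples_audio)
    samples = carrier.copy()
    samples[:n_windows * win] *= np.repeat(envelope, win)
    return (FrameStack(frames, frame_rate=frame_rate),
            AudioTrack(samples, sample_rate=audio_spec.sample_rate))
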