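# Methods

## Signal model and estimator

A voxel time series is modelled as a realization of a power-law process
with one-sided PSD |A(f)|² = c·f^(−β). The spectral index β is estimated
in two steps:

1. **Welch PSD** — eight Hann-tapered segments at 50% overlap, per-segment
   mean removal, one-sided density normalization. The segment length is
   L = floor(2N/9) (for 900 frames, L = 200 and the frequency resolution
   is 0.005 Hz). The overlap in samples is L − floor(L/2), so exactly
   eight segments fit for odd L as well. The DC bin is excluded: the
   signals are treated as zero-mean and a power law has no defined power
   at f = 0.
2. **Log–log OLS** — ordinary least squares of log10(power) on
   log10(frequency) over frequencies strictly above 0.01 Hz and up to
   Nyquist; β is the negative slope. Base 10 is a reporting convention
   only (the slope is base-invariant; the intercept is log10 c).
   Nonpositive-power bins inside the band are excluded with a logged
   count; fewer than four usable bins is an error, as is a constant
   series (zero power everywhere — H is undefined, not 0).

The extended Hurst exponent is H′ = (β+1)/2, spanning (0, 1) for fGn
(stationary, β < 1) and (1, 2) for fBm (nonstationary, β > 1). The β = 1
boundary is assigned to fBm — the conservative choice for variance-growth
handling. `classical_hurst` provides the class-conditional convention
(H = (β+1)/2 for fGn, (β−1)/2 for fBm) for interoperability; two processes
of different class sharing a classical H have β values exactly 2 apart,
which is why the extended convention is reported.

No detrending beyond per-segment mean removal is applied: inputs are
assumed high-pass cleaned upstream. Taper, detrend and the upper fit bound
are configuration, not fidelity claims — calibration on simulated power
laws (n = 900, TR = 1 s) shows |bias(β̂)| < 0.02 and SD(β̂) ≈ 0.066 across
β ∈ [−0.5, 2].

`voxelwise_hurst` runs one vectorized Welch transform over all in-mask
voxels followed by a shared-design-matrix least-squares solve; voxels with
zero-power bins fall back to the scalar path and undefined voxels become
NaN. The result is independent of voxel processing order.

## Companion measures

**ALFF** is the sum over full-length periodogram bins inside
[0.01, 0.08] Hz of the square root of the periodogram power — the
band-limited amplitude-spectrum convention of the standard resting-state
tools. "Bandpass filtering" is realized as frequency-bin selection, which
is equivalent for a bin-wise quantity. ALFF is linear in signal amplitude
and nonnegative. **Temporal SD** is the sample standard deviation (n−1).
**Smoothing** is per-frame 3-D Gaussian convolution with FWHM given in mm
(sigma = FWHM/(2√(2 ln 2)) converted per axis to voxel units), reflect
padding at edges (map edges feed ROI means), applied before map
computation.

A caveat established during design: at *fixed total variance* the in-band
amplitude sum is not monotone in β. It peaks near β ≈ 0.9 and declines for
strongly nonstationary signals, whose power concentrates below the band's
lower edge. H′ and ALFF therefore correlate positively across voxels in
the stationary range (measured r ≈ +0.65 for β ∈ [0.2, 1.0] at default
noise) but not across the full fGn-to-fBm span of a fixed-variance
phantom. Positive H–ALFF correlations reported on real gray matter
additionally reflect coupling between persistence and overall fluctuation
amplitude, which the fixed-variance phantom deliberately lacks.

## Motion QC

Framewise displacement uses the Power convention:
FD_t = Σ|Δtrans_i| + r·Σ|Δrot_j| with head radius r = 50 mm
(configurable); rotations are radians. Subjects are excluded when any
run's mean FD is strictly above 0.15 mm. Motion matching then iterates a
paired two-sided t-test on per-subject condition means (each condition's
value is the unweighted mean over its runs): while p < 0.05, the included
subject with the largest rest-condition mean FD is removed (ties broken by
ascending subject id), and matching fails if fewer than three subjects
would remain. Identically-zero paired differences count as matched
(p = 1); zero-variance nonzero differences as maximally unmatched (p = 0).
The removal order is logged and deterministic.

## Group statistics

Voxel maps are reduced to ROI means (NaN voxels excluded with a logged
count) for whole gray matter and each network; run values are averaged to
one value per subject × condition before testing. Cross-condition
contrasts are paired two-sided t-tests (sign convention: movie − rest)
with 95% CIs from the t distribution and paired Cohen's
d = mean(diff)/SD(diff). The seven network tests form the Holm
step-down family; whole-GM is a single planned comparison reported
unadjusted. Identically zero differences return p = 1, d = 0 by
convention.

## Reliability

ICC(2,1): two-way random effects, absolute agreement, single measures,
ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) from the two-way
ANOVA mean squares. Confidence intervals resample subjects (rows) with
replacement, 1,000 replicates by default, percentile method; degenerate
replicates are dropped with a logged count. The between-condition ICC
difference applies one row resample to both condition tables per replicate
(paired bootstrap — subjects are shared across conditions, and sharing the
resample preserves that pairing); the difference is significant iff the
95% CI excludes 0. Qualitative bands: poor < 0.4, fair 0.4–0.59, good
0.6–0.74, excellent ≥ 0.75 (the conventional published edges leave
[0.74, 0.75) ambiguous; 0.75 is assigned to excellent here). Subjects with
any missing run are dropped listwise per condition.

## Stimulus features

Brightness is the per-frame mean luminance (Rec. 601 weights
0.299/0.587/0.114 for color frames; gamma handling is out of scope),
sampled at the frame rate. Audio RMS and zero-crossing rate use 1.0 s
windows with 1.0 s hop by default, giving a feature sampling rate
commensurate with a 1 s TR; ZCR counts strict sign changes with exact
zeros treated as positive, and window counts follow the floor convention
(n_windows = (n − win)//hop + 1). All three series feed the same Hurst
estimator as the BOLD data.

## Synthetic data generator

The generator produces exactly the properties the analysis measures and
nothing more — it is not a hemodynamic model, and passing tests say
nothing about the biology of real BOLD, only about the pipeline's
correctness on signals with known ground truth.

* **Power-law series** — spectral synthesis: independent complex Gaussian
  Fourier coefficients with amplitude ∝ f^(−β/2), Hermitian symmetry,
  inverse FFT, rescale to the requested sample variance, DC = 0. This
  matches the PSD-based estimator's model directly; exact-covariance fGn
  (Davies–Harte circulant embedding) would be a drop-in alternative but is
  not needed for PSD-domain validation. Calibration: mean β̂ within 0.02
  of target across β ∈ [−0.5, 2] (n = 900).
* **Phantom cohorts** — default 16×16×8 grid (desk-scale stand-in for a
  full acquisition), 900 frames at TR = 1 s, 4 runs × 2 conditions,
  24 subjects. Top and bottom slices are background (low-variance white
  noise); the interior splits into eight slabs: remaining gray matter plus
  seven networks. Baseline rest H′ per region spans 0.69–1.24 and the
  movie condition shifts H′ by +0.096 (visual), +0.022 (somatomotor),
  +0.026 (dorsal attention), −0.012 (frontoparietal), −0.010 (default),
  0 (ventral attention, limbic), +0.014 (remaining GM). Each voxel is
  (1 − ν)·power-law + ν·white with unit-variance components and
  ν = 0.05 by default — the phantom emulates ICA-FIX-cleaned, smoothed
  data, where residual white noise is small. Known limitation: the white
  admixture flattens the spectral tail and attenuates estimated β
  differences progressively with β; at ν ≈ 0.2 a −0.010 H′ effect at
  H′ ≈ 1.24 is attenuated to the point of sign instability. Per-subject
  Gaussian β offsets (SD 0.05, shared across conditions and runs) provide
  between-subject variance; per-run offsets (SD 0.03) provide run-to-run
  state variability. Together these place ICC(2,1) of region-mean H′ in
  the "good" band (between-subject SD 0.025 vs within-subject ≈ 0.017 in
  H′ units). No spatial autocorrelation, hemodynamic response or
  physiological confounds are simulated.
* **Motion** — a unit-variance power-law series of index `fd_beta` is
  mapped affinely to a nonnegative FD trace with the requested mean
  (clip at zero is a < 1e−4 tail event; the trace is rescaled to the exact
  target mean) and realized as sign-alternating x-translation increments,
  so FD recomputed from the parameters reproduces the trace exactly.
  Default mean FD 0.12 mm, white increments (FD H′ ≈ 0.5).
* **Stimulus** — spatially uniform frames whose mean luminance follows a
  power law (default β = 1.588, i.e. H′ ≈ 1.29 after estimation), and
  white-noise audio amplitude-modulated by a power-law envelope (default
  RMS β = 0.68). ZCR of the white carrier is approximately constant, so
  only brightness and RMS carry injected fractal structure.

All generators are deterministic given their seed; phantom runs draw from
independently spawned per-run streams, so lazy iteration order does not
affect the data.

## Problem sizes

Defaults used by the test suite: 200 realizations for estimator
calibration anchors; 20 phantom cohorts of 24 subjects for end-to-end
effect recovery; 100 random tables for the ICC oracle; 1,000 random
7-vectors for the Holm oracle. These sizes give stable means (SE of the
calibration anchors ≈ 0.005) while keeping the full suite desk-scale.
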