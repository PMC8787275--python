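# fractalbold

Fractal analysis of fMRI BOLD signal: spectral-index estimation via Welch
power spectra, the extended Hurst exponent, and the full study pipeline
around it — ALFF and temporal-SD maps, framewise-displacement motion QC
with cross-condition matching, network-level paired statistics with Holm
correction, ICC(2,1) test-retest reliability, movie stimulus features, and
a synthetic phantom generator that makes every stage testable without any
imaging download.

## The science

Many neural and behavioural time series are *scale-free*: their one-sided
power spectral density follows a power law,

    |A(f)|^2 ∝ c · f^(−β),

where the spectral index β is the negative slope of the PSD on log–log
axes. β encodes the signal class — fractional Gaussian noise (fGn,
stationary, β < 1) versus fractional Brownian motion (fBm, nonstationary,
β > 1) — and maps onto the Hurst exponent. The classical, class-conditional
convention is H = (β+1)/2 for fGn and H = (β−1)/2 for fBm, both in (0, 1);
because two processes of different class with the same classical H have β
values exactly 2 apart, this package reports the *extended* Hurst exponent

    H′ = (β + 1) / 2,   H′ ∈ (0, 1) for fGn,  H′ ∈ (1, 2) for fBm,

which carries the class in its value. H′ = 0.5 is uncorrelated white
noise; larger values mean more persistent, more strongly fractal dynamics.

The estimator mirrors the standard BOLD protocol: Welch's periodogram with
eight Hann-tapered windows at 50% overlap, then an OLS fit of log10 power
against log10 frequency restricted to f > 0.01 Hz (up to Nyquist); β is
the negative slope. Companion measures are ALFF (the amplitude-spectrum
sum over 0.01–0.08 Hz) and temporal SD. Cohort construction excludes
subjects whose mean framewise displacement exceeds 0.15 mm in any run and
then greedily removes the highest-motion rest subjects until movie and
rest motion no longer differ (paired t, α = 0.05). Condition contrasts are
paired t-tests over gray matter and seven canonical networks, Holm-adjusted
across the network family; run-to-run reliability is ICC(2,1) (two-way
random effects, absolute agreement, single measures) with subject-resampling
bootstrap percentile intervals.

## Worked example

```python
import numpy as np
from fractalbold import (PowerLawSpec, synthesize_power_law, estimate_hurst,
                         default_phantom_design, iter_phantom_runs,
                         phantom_atlas, voxelwise_hurst, roi_means_table,
                         subject_condition_means, network_cross_condition)

# 1. a single series with a known spectral index
series = synthesize_power_law(PowerLawSpec(beta_target=0.9, n_samples=900, seed=1))
fit = estimate_hurst(series)
print(f"beta={fit.beta:.3f}  H'={fit.hurst_extended:.3f}  class={fit.signal_class}")
# beta=0.822  H'=0.911  class=fGn

# 2. a small phantom cohort end to end
design = default_phantom_design(n_subjects=8, seed=0)
atlas = phantom_atlas(design)
records = ((r.subject_id, r.condition, r.run, voxelwise_hurst(r.volume, atlas))
           for r in iter_phantom_runs(design))
table = subject_condition_means(roi_means_table(records, atlas))
stats = network_cross_condition(
    table, family=["Vis", "SoM", "DAtt", "VAtt", "Lim", "FP", "DN"])
print(stats[["region", "mean_difference", "p_adjusted"]].head(4).to_string(index=False))
# region  mean_difference   p_adjusted
#     GM         0.018315 9.907996e-07
#   DAtt         0.026177 3.103121e-03
#     DN        -0.005836 4.672246e-01
#     FP        -0.011364 1.266362e-02
```

The first block simulates a stationary power-law series (β = 0.9) and
recovers it: H′ ≈ 0.91 marks a persistent but stationary (fGn) signal
(single-realization estimates scatter around the target with SD ≈ 0.07 in
β). The second builds an eight-subject phantom in which movie-watching
shifts H′ up in the visual, somatomotor and dorsal-attention networks and
down in the frontoparietal and default networks, runs the voxelwise
estimator, and recovers the injected signs; at n = 8 subjects the smallest
effect (default network, ΔH′ = −0.010) does not reach Holm-adjusted
significance, while the larger ones do (the full-scale recovery at n = 24
is exercised in `tests/test_acceptance.py`).

A command-line interface mirrors the main steps
(`fractalbold simulate | hurst | alff | smooth | qc | roistats | icc`);
see `fractalbold --help`.

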