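"""Test-retest reliability via ICC(2,1) with bootstrap percentile intervals.

The intraclass correlation uses the two-way random-effects, absolute-
agreement, single-measures model: with subjects as rows and runs as raters,

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

where MSR, MSC and MSE are the between-subject, between-rater and residual
mean squares of the two-way ANOVA decomposition.  Confidence intervals come
from resampling subjects (rows) with replacement and taking percentiles;
the between-condition ICC difference uses a paired bootstrap in which one
row resample is applied to both condition tables, preserving the
within-subject pairing.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
import pandas as pd

from .containers import ICCDifference, ICCEstimate

__all__ = [
    "RaterTable",
    "icc_2_1",
    "icc_bootstrap_ci",
    "icc_difference_ci",
    "interpret_icc",
]

logger = logging.getLogger(__name__)

#: Conventional qualitative bands for ICC values.  The published band edges
#: ("good 0.6-0.74, excellent > 0.75") leave [0.74, 0.75) ambiguous; this
#: implementation treats the good band as [0.6, 0.75) and excellent as
#: >= 0.75.
ICC_BANDS = ((0.4, "poor"), (0.6, "fair"), (0.75, "good"))


def interpret_icc(icc: float) -> str:
    for upper, name in ICC_BANDS:
        if icc < upper:
            return name
    return "excellent"


def as_rater_table(table: Union[np.ndarray, pd.DataFrame]) -> np.ndarray:
    """Validate a subjects x raters table; rows with missing cells are
    dropped listwise with a logged count."""
    mat = np.asarray(table, dtype=float)
    if mat.ndim != 2:
        raise ValueError("rater table must be 2-D (subjects x raters)")
    complete = ~np.isnan(mat).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d subjects with missing runs", n_dropped)
        mat = mat[complete]
    n, k = mat.shape
    if k < 2:
        raise ValueError("need at least 2 raters (runs)")
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    return mat


# Backwards-friendly alias used in signatures below.
RaterTable = Union[np.ndarray, pd.DataFrame]


def icc_2_1(table: RaterTable) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures."""
    mat = as_rater_table(table)
    n, k = mat.shape
    grand = mat.mean()
    if np.ptp(mat) == 0:
        raise ValueError("zero total variance: ICC undefined")
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = (np.sum((mat - grand) ** 2)
           - k * np.sum((row_means - grand) ** 2)
           - n * np.sum((col_means - grand) ** 2))
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("degenerate table: ICC denominator is zero")
    return float((msr - mse) / denom)


def icc_bootstrap_ci(table: RaterTable, n_boot: int = 1000,
                     seed: Optional[int] = None) -> ICCEstimate:
    """ICC(2,1) with a subject-resampling bootstrap percentile 95% CI.

    Degenerate replicates (zero variance after resampling) are dropped with
    a logged count.  Deterministic given ``seed``.
    """
    mat = as_rater_table(table)
    point = icc_2_1(mat)
    rng = np.random.default_rng(seed)
    n = mat.shape[0]
    reps = []
    n_degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(icc_2_1(mat[idx]))
        except ValueError:
            n_degenerate += 1
    if n_degenerate:
        logger.info("dropped %d degenerate bootstrap replicates", n_degenerate)
    if not reps:
        raise ValueError("all bootstrap replicates were degenerate")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return ICCEstimate(icc=point, ci95=(float(lo), float(hi)),
                       n_boot=len(reps), interpretation=interpret_icc(point))


def icc_difference_ci(table_a: RaterTable, table_b: RaterTable,
                      n_boot: int = 1000, seed: Optional[int] = None
                      ) -> ICCDifference:
    """Paired-bootstrap percentile CI of ICC(table_a) - ICC(table_b).

    The same subject resample is applied to both tables in each replicate
    (subjects are shared across conditions), and the difference is declared
    significant iff the 95% CI excludes zero.
    """
    a = as_rater_table(table_a)
    b = as_rater_table(table_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("tables must contain the same subjects (same rows)")
    icc_a = icc_2_1(a)
    icc_b = icc_2_1(b)
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    diffs = []
    n_degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            diffs.append(icc_2_1(a[idx]) - icc_2_1(b[idx]))
        except ValueError:
            n_degenerate += 1
    if n_degenerate:
        logger.info("dropped %d degenerate bootstrap replicates", n_degenerate)
    if not diffs:
        raise ValueError("all bootstrap replicates were degenerate")
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return ICCDifference(
        icc_a=icc_a, icc_b=icc_b, difference=icc_a - icc_b,
        ci95=(float(lo), float(hi)),
        significant=bool(lo > 0 or hi < 0),
        n_boot=len(diffs),
    )
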