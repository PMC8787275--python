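"""Motion quality control: framewise displacement, exclusion, motion matching.

Framewise displacement (FD) follows the Power convention: the sum of the
absolute frame-to-frame changes of the three translations (mm) plus the
three rotations converted to arc length on a 50 mm sphere.  Subjects are
excluded when any run's mean FD exceeds a threshold (default 0.15 mm,
strict inequality).  Because movie and rest runs can differ systematically
in motion, ``motion_match`` then iteratively removes the subject with the
highest rest-condition mean FD until a paired t-test across conditions is
no longer significant, leaving a motion-matched cohort.

Cohort tables are pandas DataFrames with columns
``subject_id, condition, run, mean_fd, included, exclusion_reason``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MotionTrace, ScalingFit, UniformTimeSeries
from . import spectral_hurst

__all__ = [
    "framewise_displacement",
    "build_cohort_table",
    "apply_exclusion",
    "motion_match",
    "MotionMatchResult",
    "fd_hurst",
    "DEFAULT_HEAD_RADIUS_MM",
    "DEFAULT_FD_THRESHOLD_MM",
    "COHORT_COLUMNS",
]

logger = logging.getLogger(__name__)

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.15

COHORT_COLUMNS = ["subject_id", "condition", "run", "mean_fd",
                  "included", "exclusion_reason"]


def framewise_displacement(params: Union[np.ndarray, pd.DataFrame],
                           head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
                           ) -> MotionTrace:
    """FD per frame transition from a (frames, 6) motion-parameter table.

    Columns are translations x/y/z in mm then rotations x/y/z in radians.
    FD_t = sum_i |delta trans_i| + sum_j |head_radius * delta rot_j|.
    """
    if isinstance(params, pd.DataFrame):
        arr = params.to_numpy(dtype=float)
    else:
        arr = np.asarray(params, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion parameters must have shape (frames, 6)")
    if arr.shape[0] < 2:
        raise ValueError("need at least two frames to compute FD")
    if not np.all(np.isfinite(arr)):
        raise ValueError("motion parameters contain non-finite values")
    delta = np.abs(np.diff(arr, axis=0))
    fd = delta[:, :3].sum(axis=1) + head_radius_mm * delta[:, 3:].sum(axis=1)
    return MotionTrace(params=arr, fd=fd, mean_fd=float(fd.mean()))


def build_cohort_table(records: Sequence[Tuple[str, str, int, float]]
                       ) -> pd.DataFrame:
    """Cohort table from (subject_id, condition, run, mean_fd) records."""
    df = pd.DataFrame(records,
                      columns=["subject_id", "condition", "run", "mean_fd"])
    df["included"] = True
    df["exclusion_reason"] = None
    return df[COHORT_COLUMNS]


def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    return cohort.copy()


def apply_exclusion(cohort: pd.DataFrame,
                    threshold: float = DEFAULT_FD_THRESHOLD_MM,
                    expected_runs: Optional[int] = None) -> pd.DataFrame:
    """Exclude subjects with mean FD strictly above ``threshold`` in any run.

    A run at exactly the threshold does not exclude.  If ``expected_runs``
    is given (runs per condition), subjects with missing runs are flagged
    ``incomplete_runs`` rather than silently dropped.  Idempotent: existing
    exclusion reasons from other stages are preserved.
    """
    out = _check_cohort(cohort)
    for subject, rows in out.groupby("subject_id"):
        if (rows["mean_fd"] > threshold).any():
            out.loc[out["subject_id"] == subject, "included"] = False
            out.loc[out["subject_id"] == subject, "exclusion_reason"] = (
                f"mean_fd>{threshold}")
        elif expected_runs is not None:
            counts = rows.groupby("condition")["run"].nunique()
            if (counts != expected_runs).any() or counts.size == 0:
                out.loc[out["subject_id"] == subject, "included"] = False
                out.loc[out["subject_id"] == subject,
                        "exclusion_reason"] = "incomplete_runs"
    return out


def _condition_means(cohort: pd.DataFrame, conditions: Tuple[str, str]
                     ) -> pd.DataFrame:
    """Per-subject mean FD per condition, included subjects only.

    Each condition's value is the unweighted mean of that condition's runs.
    """
    inc = cohort[cohort["included"]]
    pivot = (inc.groupby(["subject_id", "condition"])["mean_fd"].mean()
             .unstack("condition"))
    for cond in conditions:
        if cond not in pivot.columns:
            raise ValueError(f"no included runs for condition {cond!r}")
    pivot = pivot[list(conditions)].dropna()
    return pivot


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    if np.ptp(diff) == 0:
        # all subjects shifted identically: matched if the shift is zero,
        # otherwise maximally unmatched
        return 1.0 if np.allclose(diff, 0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class MotionMatchResult:
    """Outcome of the motion-matching loop."""

    cohort: pd.DataFrame
    removed: List[str] = field(default_factory=list)
    p_history: List[float] = field(default_factory=list)

    @property
    def p_final(self) -> float:
        return self.p_history[-1]

    @property
    def n_retained(self) -> int:
        return int(self.cohort.loc[self.cohort["included"],
                                   "subject_id"].nunique())


def motion_match(cohort: pd.DataFrame, alpha: float = 0.05,
                 conditions: Tuple[str, str] = ("movie", "rest"),
                 remove_from: str = "rest") -> MotionMatchResult:
    """Equalize mean FD across conditions by greedy subject removal.

    While the paired two-sided t-test on per-subject (movie, rest) mean FD
    is significant at ``alpha``, remove the included subject with the
    largest ``remove_from``-condition mean FD (ties broken by ascending
    subject_id), then retest.  Deterministic given the table.

    Raises
    ------
    RuntimeError
        If fewer than three subjects would remain before the test passes.
    """
    out = _check_cohort(cohort)
    result = MotionMatchResult(cohort=out)
    if remove_from not in conditions:
        raise ValueError("remove_from must be one of the tested conditions")
    while True:
        means = _condition_means(out, conditions)
        if len(means) < 3:
            raise RuntimeError(
                "motion matching exhausted the cohort (fewer than 3 subjects)")
        p = _paired_p(means[conditions[0]].to_numpy(),
                      means[conditions[1]].to_numpy())
        result.p_history.append(p)
        if p >= alpha:
            break
        ranked = means.reset_index().sort_values(
            [remove_from, "subject_id"], ascending=[False, True],
            kind="stable")
        victim = ranked.iloc[0]["subject_id"]
        out.loc[out["subject_id"] == victim, "included"] = False
        out.loc[out["subject_id"] == victim,
                "exclusion_reason"] = "motion_match"
        result.removed.append(victim)
        logger.info("motion_match removed %s (p=%.4g)", victim, p)
    result.cohort = out
    return result


def fd_hurst(trace: MotionTrace, tr: float = 1.0, **params) -> ScalingFit:
    """Extended-Hurst fit of the FD series (sampled once per TR)."""
    series = UniformTimeSeries(trace.fd, sampling_interval=tr)
    return spectral_hurst.estimate_hurst(series, **params)
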