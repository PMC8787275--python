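"""ROI aggregation and cross-condition inference.

Voxel maps (H', ALFF, SD) are reduced to region means over a label atlas —
whole gray matter (all nonzero labels) plus the seven canonical networks —
then compared between conditions with paired two-sided Student t-tests.
The seven network tests form the multiple-comparison family and are
Holm-adjusted; the whole-gray-matter test is reported unadjusted, as a
single planned comparison outside the family.

Effect sizes are paired Cohen's d = mean(diff) / SD(diff).  The sign
convention everywhere is movie minus rest.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    CorrelationResult,
    LabelAtlas,
    PairedComparison,
    VoxelMap,
)

__all__ = [
    "roi_mean",
    "roi_means_table",
    "subject_condition_means",
    "paired_compare",
    "holm_adjust",
    "correlate",
    "network_cross_condition",
    "GM_REGION",
]

logger = logging.getLogger(__name__)

#: Pseudo-label for the whole-gray-matter ROI (union of all nonzero labels).
GM_REGION = "GM"


def roi_mean(voxel_map: VoxelMap, atlas: LabelAtlas,
             label: Optional[int] = None) -> float:
    """Mean over in-label, non-NaN voxels.

    ``label=None`` means the whole-gray-matter ROI (all nonzero labels).
    NaN voxels (undefined fits) are excluded with a logged count.
    """
    if voxel_map.data.shape != atlas.grid_shape:
        raise ValueError("map grid does not match atlas grid")
    region = atlas.labels > 0 if label is None else atlas.labels == label
    if not region.any():
        raise ValueError(f"label {label!r} selects no voxels")
    vals = voxel_map.data[region]
    n_nan = int(np.isnan(vals).sum())
    if n_nan:
        logger.info("roi_mean: %d undefined voxels excluded from label %r",
                    n_nan, label)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"label {label!r} has no defined voxels")
    return float(vals.mean())


def roi_means_table(records: Iterable[Tuple[str, str, int, VoxelMap]],
                    atlas: LabelAtlas) -> pd.DataFrame:
    """Long table of ROI means, one row per (subject, condition, run, region).

    ``records`` yields (subject_id, condition, run, voxel_map).  Regions are
    the whole-GM ROI plus every labelled region in the atlas legend.
    """
    labels = atlas.region_labels()
    rows = []
    for subject_id, condition, run, vmap in records:
        rows.append((subject_id, condition, run, GM_REGION,
                     roi_mean(vmap, atlas, None)))
        for label in labels:
            name = atlas.legend.get(label, f"region-{label}")
            rows.append((subject_id, condition, run, name,
                         roi_mean(vmap, atlas, label)))
    return pd.DataFrame(
        rows, columns=["subject_id", "condition", "run", "region", "value"])


def subject_condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Average the runs of each condition: one value per
    (subject, condition, region)."""
    return (table.groupby(["subject_id", "condition", "region"],
                          as_index=False)["value"].mean())


def paired_compare(values_a: Sequence[float], values_b: Sequence[float],
                   region: str = "", p_adjusted: Optional[float] = None
                   ) -> PairedComparison:
    """Paired two-sided t-test of a (movie) against b (rest).

    Returns the mean difference a - b, t, raw p, 95% CI of the mean
    difference, and paired Cohen's d = mean(diff)/SD(diff).  Identically
    zero differences return t = 0, p = 1, d = 0 by convention; zero-variance
    nonzero differences are an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0:
        if mean != 0:
            raise ValueError("zero-variance nonzero differences: the paired "
                             "t statistic is undefined")
        return PairedComparison(region=region, mean_difference=0.0,
                                t_statistic=0.0, p_raw=1.0,
                                p_adjusted=1.0 if p_adjusted is None else p_adjusted,
                                ci95=(0.0, 0.0), effect_size_d=0.0, n=n)
    t_stat, p_raw = stats.ttest_rel(a, b)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return PairedComparison(
        region=region,
        mean_difference=mean,
        t_statistic=float(t_stat),
        p_raw=float(p_raw),
        p_adjusted=float(p_raw) if p_adjusted is None else float(p_adjusted),
        ci95=(mean - half, mean + half),
        effect_size_d=mean / sd,
        n=n,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Equivalent to sorting ascending, taking the running maximum of
    (m - rank) * p, and capping at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return adjusted


def correlate(x: Sequence[float], y: Sequence[float],
              pair: Tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("samples must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(r), p=float(p), n=x.size)


def network_cross_condition(subject_table: pd.DataFrame,
                            condition_a: str = "movie",
                            condition_b: str = "rest",
                            gm_region: str = GM_REGION,
                            family: Optional[Sequence[str]] = None
                            ) -> pd.DataFrame:
    """Paired movie-vs-rest comparison for GM and each network region.

    ``subject_table`` is the output of :func:`subject_condition_means`.
    ``family`` names the regions forming the Holm multiple-comparison
    family (default: every region except GM, i.e. the networks); regions
    outside the family — GM in particular — are single planned comparisons
    and keep their raw p as adjusted p.

    Returns one row per region with all :class:`PairedComparison` fields.
    """
    pivot = subject_table.pivot_table(
        index="subject_id", columns=["region", "condition"], values="value")
    regions = sorted({r for r, _ in pivot.columns})
    if family is None:
        networks = [r for r in regions if r != gm_region]
    else:
        missing = set(family) - set(regions)
        if missing:
            raise ValueError(f"family regions {sorted(missing)} not in table")
        networks = [r for r in regions if r in set(family)]

    raw: Dict[str, PairedComparison] = {}
    for region in regions:
        a = pivot[(region, condition_a)].dropna()
        b = pivot[(region, condition_b)].dropna()
        common = a.index.intersection(b.index)
        raw[region] = paired_compare(a.loc[common], b.loc[common],
                                     region=region)

    adj = holm_adjust([raw[r].p_raw for r in networks]) if networks else []
    adjusted: Dict[str, float] = dict(zip(networks, adj))

    rows = []
    others = [r for r in regions if r != gm_region and r not in networks]
    order = ([gm_region] if gm_region in raw else []) + networks + others
    for region in order:
        c = raw[region]
        p_adj = adjusted.get(region, c.p_raw)
        rows.append({
            "region": region,
            "n": c.n,
            "mean_difference": c.mean_difference,
            "t_statistic": c.t_statistic,
            "p_raw": c.p_raw,
            "p_adjusted": p_adj,
            "ci95_low": c.ci95[0],
            "ci95_high": c.ci95[1],
            "effect_size_d": c.effect_size_d,
            "corrected": region in adjusted,
        })
    return pd.DataFrame(rows)
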