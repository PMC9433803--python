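"""Associations between burst onsets and learning-population graph metrics.

Covers the three headline quantifications: per-cluster regression of burst
counts on the mean node metric of nearby learning electrodes, overlap between
onset electrodes and the top-ranked learning electrodes, and Welch-t pre/post
comparisons of summary series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .core import ElectrodeGrid
from .errors import ConfigError
from .propagation import OnsetCluster

__all__ = [
    "RegressionResult",
    "ComparisonRow",
    "metric_burst_regression",
    "top_percentile_overlap",
    "pre_post_compare",
]

DEFAULT_LINK_RADIUS = 115.0  # μm


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    n_clusters: int
    n_excluded: int
    metric_name: str


def metric_burst_regression(
    clusters: Sequence[OnsetCluster],
    node_metric: Dict[int, float],
    grid: ElectrodeGrid,
    metric_name: str = "betweenness",
    link_radius: float = DEFAULT_LINK_RADIUS,
) -> Optional[RegressionResult]:
    """OLS of cluster burst counts on the mean metric of learning electrodes
    within ``link_radius`` of the cluster centroid.

    Clusters with no linked learning electrode are excluded (and counted).
    Returns None when fewer than three linked clusters remain or the metric is
    constant across them.
    """
    if not node_metric:
        raise ConfigError("empty node metric")
    electrodes = sorted(node_metric)
    tree = cKDTree(grid.positions(electrodes))
    xs: List[float] = []
    ys: List[float] = []
    excluded = 0
    for c in clusters:
        idx = tree.query_ball_point(np.asarray(c.centroid, dtype=float), link_radius)
        if not idx:
            excluded += 1
            continue
        xs.append(float(np.mean([node_metric[electrodes[i]] for i in idx])))
        ys.append(float(c.burst_count))
    if len(xs) < 3:
        warnings.warn("fewer than 3 linked clusters: regression undefined", stacklevel=2)
        return None
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.std() == 0:
        warnings.warn("metric constant across clusters: regression undefined", stacklevel=2)
        return None
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    r = 0.0 if syy == 0 else sxy / np.sqrt(sxx * syy)
    return RegressionResult(
        slope=float(slope),
        intercept=float(y.mean() - slope * x.mean()),
        r=float(r),
        r2=float(r * r),
        n_clusters=len(xs),
        n_excluded=excluded,
        metric_name=metric_name,
    )


def top_percentile_overlap(
    onset_electrodes: Sequence[int],
    node_metric: Dict[int, float],
    grid: ElectrodeGrid,
    percentile_keep: float = 0.9,
    link_radius: float = DEFAULT_LINK_RADIUS,
) -> float:
    """Fraction of onset electrodes mapping into the top-ranked learning set.

    The top set keeps the highest ``percentile_keep`` of learning electrodes
    by metric value (ties at the cut kept).  Onset electrodes outside the
    learning set map to their nearest learning electrode within
    ``link_radius``; unmapped onsets count as non-overlap.
    """
    onsets = sorted({int(e) for e in onset_electrodes})
    if not onsets:
        raise ConfigError("empty onset set")
    if not node_metric:
        raise ConfigError("empty learning metric set")
    if not 0 < percentile_keep <= 1:
        raise ConfigError("percentile_keep must be in (0, 1]")
    electrodes = sorted(node_metric)
    values = np.array([node_metric[e] for e in electrodes])
    cut = float(np.quantile(values, 1.0 - percentile_keep))
    top = {e for e, v in zip(electrodes, values) if v >= cut}
    if not top:
        warnings.warn("empty top set", stacklevel=2)
        return 0.0
    tree = cKDTree(grid.positions(electrodes))
    learning_set = set(electrodes)
    hits = 0
    for e in onsets:
        if e in learning_set:
            mapped = e
        else:
            d, i = tree.query(grid.position(e))
            if d > link_radius:
                continue
            mapped = electrodes[int(i)]
        if mapped in top:
            hits += 1
    return hits / len(onsets)


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    mean_pre: float
    mean_post: float
    se_pre: float
    se_post: float
    t: float
    p: float
    n_pre: int
    n_post: int
    degenerate: bool = False


def pre_post_compare(series_pre, series_post, label: str = "") -> ComparisonRow:
    """Welch two-sample t-test with means +/- standard errors.

    Zero variance in both samples falls back to an exact-equality report
    (t = 0, p = 1 when means agree; flagged degenerate otherwise).
    """
    a = np.asarray(series_pre, dtype=float)
    b = np.asarray(series_post, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("both samples need n >= 2")
    se_a = float(a.std(ddof=1) / np.sqrt(a.size))
    se_b = float(b.std(ddof=1) / np.sqrt(b.size))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = a.mean() == b.mean()
        return ComparisonRow(
            label=label, mean_pre=float(a.mean()), mean_post=float(b.mean()),
            se_pre=se_a, se_post=se_b,
            t=0.0 if equal else float("inf"), p=1.0 if equal else 0.0,
            n_pre=int(a.size), n_post=int(b.size), degenerate=not equal,
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonRow(
        label=label, mean_pre=float(a.mean()), mean_post=float(b.mean()),
        se_pre=se_a, se_post=se_b, t=float(t), p=float(p),
        n_pre=int(a.size), n_post=int(b.size),
    )
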