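"""Burst initiation and propagation mapping.

Each burst's electrodes are ranked by first-spike time (ties broken by
(row, col)); the ten earliest-ranked electrodes are the onset electrodes and
their mean center position is the initiation site.  A distance-latency
regression over all participating electrodes estimates propagation speed, and
initiation sites are related to the learning population by nearest-neighbour
distance and single-linkage clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .bursts import NetworkBurst
from .core import ElectrodeGrid
from .errors import ConfigError
from .learning import TrendFit

__all__ = [
    "PropagationEntry",
    "OnsetCluster",
    "rank_order_map",
    "initiation_site",
    "distance_latency_fit",
    "nearest_learning_distance",
    "distance_distribution",
    "cluster_onsets",
    "analyze_bursts",
    "propagation_frame",
]

N_ONSET = 10  # earliest recruitment ranks defining the burst onset


@dataclass
class PropagationEntry:
    burst_id: int
    rank_order: Dict[int, int]  # electrode -> rank, 1 = earliest
    onset_electrodes: List[int]
    site: np.ndarray  # (x, y) μm
    fit: Optional[TrendFit]  # latency on distance; slope in ms/μm
    nearest_learning_um: Optional[float] = None
    cluster_id: Optional[int] = None


@dataclass
class OnsetCluster:
    cluster_id: int
    burst_ids: List[int]
    centroid: np.ndarray  # (x, y) μm

    @property
    def burst_count(self) -> int:
        return len(self.burst_ids)


def rank_order_map(b: NetworkBurst, grid: ElectrodeGrid) -> Dict[int, int]:
    """Electrode -> first-spike rank (1-based); ties broken by (row, col)."""
    if not b.participating_electrodes:
        raise ConfigError("burst has no participating electrodes")
    order = sorted(b.first_spike_time, key=lambda e: (b.first_spike_time[e], grid.rc(e)))
    return {e: i + 1 for i, e in enumerate(order)}


def initiation_site(rank_order: Dict[int, int], grid: ElectrodeGrid, n_onset: int = N_ONSET) -> np.ndarray:
    """Mean center position of the ``n_onset`` earliest-ranked electrodes."""
    onset = [e for e, r in sorted(rank_order.items(), key=lambda kv: kv[1])[:n_onset]]
    return grid.positions(onset).mean(axis=0)


def distance_latency_fit(b: NetworkBurst, site: np.ndarray, grid: ElectrodeGrid) -> Optional[TrendFit]:
    """OLS of first-spike latency (ms, relative to the earliest first spike)
    on distance (μm) from the initiation site; None when degenerate."""
    if len(b.first_spike_time) < 3:
        raise ConfigError("need at least 3 participating electrodes")
    electrodes = sorted(b.first_spike_time)
    pos = grid.positions(electrodes)
    dist = np.hypot(pos[:, 0] - site[0], pos[:, 1] - site[1])
    t0 = min(b.first_spike_time.values())
    lat = np.array([b.first_spike_time[e] - t0 for e in electrodes])
    if np.ptp(dist) == 0:
        return None
    mx, my = dist.mean(), lat.mean()
    dx, dy = dist - mx, lat - my
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    slope = sxy / sxx
    r = 0.0 if syy == 0 else sxy / np.sqrt(sxx * syy)
    return TrendFit(slope=float(slope), intercept=float(my - slope * mx), r=float(r),
                    r2=float(r * r), p=float("nan"), n=int(dist.size))


def nearest_learning_distance(site, learning_electrodes: Sequence[int], grid: ElectrodeGrid) -> float:
    """Minimum distance (μm) from a site to any learning-electrode center."""
    learning = list(learning_electrodes)
    if not learning:
        raise ConfigError("learning population is empty")
    pos = grid.positions(learning)
    site = np.asarray(site, dtype=float)
    return float(np.min(np.hypot(pos[:, 0] - site[0], pos[:, 1] - site[1])))


def distance_distribution(
    sites: Sequence, learning_electrodes: Sequence[int], grid: ElectrodeGrid,
    thresholds: Sequence[float] = (81.0, 115.0, 162.0),
) -> Dict[float, float]:
    """Cumulative fraction of sites within each threshold (inclusive) of the
    learning population."""
    sites = [np.asarray(s, dtype=float) for s in sites]
    if not sites:
        raise ConfigError("no sites")
    learning = list(learning_electrodes)
    if not learning:
        raise ConfigError("learning population is empty")
    tree = cKDTree(grid.positions(learning))
    d, _ = tree.query(np.vstack(sites))
    return {float(th): float(np.mean(d <= th)) for th in thresholds}


def cluster_onsets(sites: Sequence, radius: float = 81.0) -> List[OnsetCluster]:
    """Single-linkage clustering of initiation sites with a distance cutoff.

    ``sites`` is a sequence of (x, y) positions indexed by burst id.  Sites
    within ``radius`` of any member of a cluster join it; clusters are labeled
    in order of their lexicographically smallest member.
    """
    pts = np.asarray([np.asarray(s, dtype=float) for s in sites])
    if pts.size == 0:
        raise ConfigError("no sites to cluster")
    n = pts.shape[0]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(pts)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (tuple(pts[min(g)]), min(g)))
    return [
        OnsetCluster(cluster_id=ci, burst_ids=sorted(g), centroid=pts[g].mean(axis=0))
        for ci, g in enumerate(ordered)
    ]


def analyze_bursts(
    bursts: List[NetworkBurst],
    grid: ElectrodeGrid,
    learning_electrodes: Sequence[int] | None = None,
    cluster_radius: float = 81.0,
) -> tuple[List[PropagationEntry], List[OnsetCluster]]:
    """Full propagation analysis: rank maps, sites, fits, clusters, distances."""
    entries: List[PropagationEntry] = []
    for bid, b in enumerate(bursts):
        ranks = rank_order_map(b, grid)
        site = initiation_site(ranks, grid)
        fit = distance_latency_fit(b, site, grid) if len(b.first_spike_time) >= 3 else None
        near = (
            nearest_learning_distance(site, learning_electrodes, grid)
            if learning_electrodes
            else None
        )
        entries.append(
            PropagationEntry(
                burst_id=bid,
                rank_order=ranks,
                onset_electrodes=[e for e, r in sorted(ranks.items(), key=lambda kv: kv[1])[:N_ONSET]],
                site=site,
                fit=fit,
                nearest_learning_um=near,
            )
        )
    clusters: List[OnsetCluster] = []
    if entries:
        clusters = cluster_onsets([e.site for e in entries], radius=cluster_radius)
        by_burst = {bid: c.cluster_id for c in clusters for bid in c.burst_ids}
        for e in entries:
            e.cluster_id = by_burst[e.burst_id]
    return entries, clusters


def propagation_frame(entries: List[PropagationEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "burst_id": [e.burst_id for e in entries],
            "site_x_um": [e.site[0] for e in entries],
            "site_y_um": [e.site[1] for e in entries],
            "slope": [e.fit.slope if e.fit else np.nan for e in entries],
            "r2": [e.fit.r2 if e.fit else np.nan for e in entries],
            "nearest_learning_um": [
                e.nearest_learning_um if e.nearest_learning_um is not None else np.nan for e in entries
            ],
            "cluster_id": [e.cluster_id for e in entries],
        }
    )
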