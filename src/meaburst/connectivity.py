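"""Functional connectivity from spike-train cross-correlation.

The correlogram value at lag ``tau`` counts, for every spike of train x, the
spikes of train y falling within ``tau +/- delta_tau/2`` (closed interval),
scaled by the product normalization ``1/(N_x N_y)`` (a square-root variant is
available).  Edges of the functional graph are pairs whose correlogram peak
exceeds a network-wide threshold: the average correlogram value plus a
multiple of the average per-pair correlogram standard deviation.  Direction
follows the polarity of the peak lag (positive lag: x precedes y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .core import SpikeTrainSet
from .errors import ConfigError

__all__ = [
    "ConnectivityConfig",
    "CrossCorrelogram",
    "FunctionalGraph",
    "cross_correlogram",
    "build_functional_graph",
    "rate_correlation",
    "synchrony",
]


@dataclass(frozen=True)
class ConnectivityConfig:
    bin_ms: float = 1.0
    tau_max: float = 50.0
    delta_tau: float = 5.0
    normalization: str = "product"  # 'product' -> 1/(NxNy); 'sqrt' -> 1/sqrt(NxNy)
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.bin_ms <= 0 or self.tau_max <= 0 or self.delta_tau <= 0:
            raise ConfigError("bin_ms, tau_max and delta_tau must be positive")
        if self.normalization not in {"product", "sqrt"}:
            raise ConfigError("normalization must be 'product' or 'sqrt'")


@dataclass
class CrossCorrelogram:
    lags: np.ndarray
    values: np.ndarray
    n_x: int
    n_y: int
    delta_tau: float
    peak_lag: float
    peak_value: float

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std())


def _pick_peak(lags: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Tied maxima form a plateau when delta_tau spans several lag bins; take
    the plateau median (then smallest |lag|) as the deterministic peak lag."""
    vmax = values.max()
    cands = np.sort(lags[values == vmax])
    if cands.size % 2:
        best = cands[cands.size // 2]
    else:
        mid = cands[cands.size // 2 - 1 : cands.size // 2 + 1]
        best = min(mid, key=lambda l: (abs(l), l))
    return float(best), float(vmax)


def cross_correlogram(
    x,
    y,
    bin_ms: float = 1.0,
    tau_max: float = 50.0,
    delta_tau: float = 5.0,
    normalization: str = "product",
) -> CrossCorrelogram:
    """Cross-correlogram of two spike trains on a lag grid of ``bin_ms`` steps."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("cross-correlogram undefined for an empty spike train")
    if normalization not in {"product", "sqrt"}:
        raise ConfigError("normalization must be 'product' or 'sqrt'")
    n_lags = int(round(tau_max / bin_ms))
    lags = np.arange(-n_lags, n_lags + 1) * bin_ms
    half = delta_tau / 2.0
    # All pairwise differences y_j - x_i that can land in any lag window.
    reach = tau_max + half
    lo = np.searchsorted(y, x - reach, side="left")
    hi = np.searchsorted(y, x + reach, side="right")
    diffs = np.concatenate([y[a:b] - xi for xi, a, b in zip(x, lo, hi)]) if x.size else np.empty(0)
    diffs.sort()
    counts = np.searchsorted(diffs, lags + half, side="right") - np.searchsorted(diffs, lags - half, side="left")
    if normalization == "product":
        norm = x.size * y.size
    else:
        norm = np.sqrt(x.size * y.size)
    values = counts / norm
    peak_lag, peak_value = _pick_peak(lags, values)
    return CrossCorrelogram(
        lags=lags,
        values=values,
        n_x=int(x.size),
        n_y=int(y.size),
        delta_tau=delta_tau,
        peak_lag=peak_lag,
        peak_value=peak_value,
    )


@dataclass
class FunctionalGraph:
    graph: nx.DiGraph
    threshold: float
    nodes: list
    peak_values: dict  # (i, j) with i < j -> peak value
    peak_lags: dict  # (i, j) with i < j -> peak lag
    config: ConnectivityConfig = field(default_factory=ConnectivityConfig)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def undirected(self) -> nx.Graph:
        """Binarized, symmetrized view used by the graph metrics."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from((u, v) for u, v in self.graph.edges if u != v)
        return g


def build_functional_graph(
    s: SpikeTrainSet, node_electrodes: Sequence[int], cfg: ConnectivityConfig = ConnectivityConfig()
) -> FunctionalGraph:
    """Thresholded directed functional graph over the given node electrodes.

    The threshold is the network-wide mean correlogram value plus
    ``sd_multiplier`` times the average per-pair correlogram SD; a pair whose
    correlogram peak strictly exceeds it becomes an edge, directed by the sign
    of the peak lag (zero-lag peaks yield reciprocal edges).
    """
    nodes = sorted({int(e) for e in node_electrodes})
    if len(nodes) < 2:
        raise ConfigError("functional graph needs at least two nodes")
    peak_values: dict = {}
    peak_lags: dict = {}
    pair_means: list[float] = []
    pair_sds: list[float] = []
    for ai in range(len(nodes)):
        a = nodes[ai]
        ta = s.train(a)
        if ta.size == 0:
            continue
        for bi in range(ai + 1, len(nodes)):
            b = nodes[bi]
            tb = s.train(b)
            if tb.size == 0:
                continue
            cc = cross_correlogram(
                ta, tb, bin_ms=cfg.bin_ms, tau_max=cfg.tau_max, delta_tau=cfg.delta_tau,
                normalization=cfg.normalization,
            )
            peak_values[(a, b)] = cc.peak_value
            peak_lags[(a, b)] = cc.peak_lag
            pair_means.append(cc.mean)
            pair_sds.append(cc.sd)

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    if pair_means:
        threshold = float(np.mean(pair_means) + cfg.sd_multiplier * np.mean(pair_sds))
        for (a, b), v in peak_values.items():
            if v > threshold:
                lag = peak_lags[(a, b)]
                if lag > 0:
                    g.add_edge(a, b, weight=v, peak_lag=lag)
                elif lag < 0:
                    g.add_edge(b, a, weight=v, peak_lag=-lag)
                else:
                    g.add_edge(a, b, weight=v, peak_lag=0.0)
                    g.add_edge(b, a, weight=v, peak_lag=0.0)
    else:
        threshold = float("nan")
    if g.number_of_edges() == 0:
        warnings.warn("all node pairs sub-threshold: functional graph is empty", stacklevel=2)
    return FunctionalGraph(
        graph=g, threshold=threshold, nodes=nodes, peak_values=peak_values, peak_lags=peak_lags, config=cfg
    )


def rate_correlation(x, y, duration: float, bin_ms: float = 100.0) -> Optional[float]:
    """Pearson correlation of binned spike-count vectors; None when degenerate."""
    if bin_ms <= 0 or duration <= 0:
        raise ConfigError("bin_ms and duration must be positive")
    edges = np.arange(0.0, duration + bin_ms, bin_ms)
    cx, _ = np.histogram(np.asarray(x, dtype=float), bins=edges)
    cy, _ = np.histogram(np.asarray(y, dtype=float), bins=edges)
    if cx.size < 2:
        raise ConfigError("need at least two bins")
    if cx.std() == 0 or cy.std() == 0:
        warnings.warn("zero-variance rate vector: correlation undefined", stacklevel=2)
        return None
    return float(np.corrcoef(cx, cy)[0, 1])


def synchrony(x, y, tau_s: float = 10.0) -> float:
    """Symmetrized nearest-spike synchrony score in (0, 1].

    For each spike the distance to the closest spike of the other train is
    inverted as ``1 / (1 + dt / tau_s)``; the score averages over the spikes
    of both trains (both directions).
    """
    if tau_s <= 0:
        raise ConfigError("tau_s must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("synchrony undefined for an empty spike train")

    def one_way(a: np.ndarray, b: np.ndarray) -> float:
        pos = np.searchsorted(b, a)
        left = np.abs(a - b[np.clip(pos - 1, 0, b.size - 1)])
        right = np.abs(b[np.clip(pos, 0, b.size - 1)] - a)
        dt = np.minimum(left, right)
        return float(np.mean(1.0 / (1.0 + dt / tau_s)))

    return 0.5 * (one_way(x, y) + one_way(y, x))
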