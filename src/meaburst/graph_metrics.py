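"""Node and network measures on the binarized, symmetrized functional graph.

Degree, density, global efficiency, modularity, betweenness centrality and
small-worldness.  Betweenness is normalized over unordered node pairs by
``(n-1)(n-2)``, so the middle node of a three-node path scores 0.5.
Small-worldness compares clustering and characteristic path length against
degree-preserving rewired null graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import networkx as nx
import numpy as np

from .errors import ConfigError, NullModelError

__all__ = [
    "degree",
    "density",
    "global_efficiency",
    "modularity",
    "detect_communities",
    "betweenness",
    "small_world",
    "SmallWorldResult",
    "GraphMetrics",
    "compute_graph_metrics",
]


def _as_simple_graph(g) -> nx.Graph:
    """Binarized, symmetrized simple graph without self-loops."""
    if hasattr(g, "graph") and not isinstance(g, nx.Graph):  # FunctionalGraph wrapper
        g = g.graph
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from((u, v) for u, v in g.edges if u != v)
    return h


def degree(g) -> Dict:
    """Per-node degree (row sums of the binarized symmetric adjacency)."""
    return dict(_as_simple_graph(g).degree())


def density(g) -> float:
    """2l / (n(n-1)); undefined below two nodes."""
    h = _as_simple_graph(g)
    n = h.number_of_nodes()
    if n < 2:
        raise ConfigError("density undefined for fewer than 2 nodes")
    return 2.0 * h.number_of_edges() / (n * (n - 1))


def global_efficiency(g) -> float:
    """Average inverse shortest-path length, with 1/inf := 0."""
    return float(nx.global_efficiency(_as_simple_graph(g)))


def _validate_partition(h: nx.Graph, partition: Sequence[Set]) -> List[Set]:
    mods = [set(m) for m in partition]
    seen: Set = set()
    for m in mods:
        if m & seen:
            raise ConfigError("partition modules overlap")
        seen |= m
    if seen != set(h.nodes):
        raise ConfigError("partition must cover all nodes exactly")
    return mods


def modularity(g, partition: Sequence[Set]) -> float:
    """Q = sum_u [e_uu - (sum_v e_uv)^2] over the module mixing matrix.

    ``e_uu`` is the fraction of links internal to module u; off-diagonal
    entries split each between-module link across both orientations so the
    matrix sums to one.
    """
    h = _as_simple_graph(g)
    mods = _validate_partition(h, partition)
    m = h.number_of_edges()
    if m == 0:
        return 0.0
    label = {node: ui for ui, mod in enumerate(mods) for node in mod}
    k = len(mods)
    e = np.zeros((k, k))
    for u, v in h.edges:
        a, b = label[u], label[v]
        if a == b:
            e[a, a] += 1.0 / m
        else:
            e[a, b] += 0.5 / m
            e[b, a] += 0.5 / m
    row = e.sum(axis=1)
    return float(np.sum(np.diag(e) - row**2))


def detect_communities(g, seed: int | None = None) -> List[Set]:
    """Greedy modularity-maximizing partition, deterministically ordered."""
    h = _as_simple_graph(g)
    if h.number_of_edges() == 0:
        return [{n} for n in sorted(h.nodes)]
    comms = nx.community.greedy_modularity_communities(h)
    return sorted((set(c) for c in comms), key=lambda c: min(c))


def betweenness(g) -> Dict:
    """Shortest-path betweenness over unordered pairs, normalized by (n-1)(n-2)."""
    h = _as_simple_graph(g)
    n = h.number_of_nodes()
    if n < 3:
        warnings.warn("betweenness undefined for fewer than 3 nodes; returning zeros", stacklevel=2)
        return {v: 0.0 for v in h.nodes}
    raw = nx.betweenness_centrality(h, normalized=False)
    scale = 1.0 / ((n - 1) * (n - 2))
    return {v: raw[v] * scale for v in h.nodes}


@dataclass(frozen=True)
class SmallWorldResult:
    s: float
    clustering: float
    path_length: float
    clustering_rand: float
    path_length_rand: float
    n_nulls: int


def _largest_component(h: nx.Graph) -> nx.Graph:
    comp = max(nx.connected_components(h), key=len)
    return h.subgraph(comp).copy()


def small_world(g, n_nulls: int = 20, seed: int | None = 0, n_swaps_factor: int = 10) -> SmallWorldResult:
    """S = (C / C_rand) / (L / L_rand) on the largest connected component.

    Null statistics are means over ``n_nulls`` degree-preserving rewirings
    (``n_swaps_factor * |edges|`` double-edge swaps each).
    """
    if n_nulls < 1:
        raise ConfigError("n_nulls must be >= 1")
    h = _largest_component(_as_simple_graph(g))
    m = h.number_of_edges()
    if h.number_of_nodes() < 4 or m < 2:
        raise NullModelError("graph too small to rewire")
    c_obs = nx.average_clustering(h)
    l_obs = nx.average_shortest_path_length(h)
    rng = np.random.default_rng(seed)
    c_rand: list[float] = []
    l_rand: list[float] = []
    for _ in range(n_nulls):
        null = h.copy()
        try:
            nx.double_edge_swap(
                null, nswap=n_swaps_factor * m, max_tries=100 * n_swaps_factor * m,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXError as exc:
            raise NullModelError(f"degree-preserving rewiring failed: {exc}") from exc
        c_rand.append(nx.average_clustering(null))
        nl = _largest_component(null)
        l_rand.append(nx.average_shortest_path_length(nl))
    c_r = float(np.mean(c_rand))
    l_r = float(np.mean(l_rand))
    if c_r == 0 or l_obs == 0:
        raise NullModelError("degenerate null model (zero clustering or path length)")
    s = (c_obs / c_r) / (l_obs / l_r)
    return SmallWorldResult(
        s=float(s), clustering=float(c_obs), path_length=float(l_obs),
        clustering_rand=c_r, path_length_rand=l_r, n_nulls=n_nulls,
    )


@dataclass
class GraphMetrics:
    degree: Dict
    betweenness: Dict
    density: float
    n_nodes: int
    n_links: int
    global_efficiency: float
    modularity: float
    partition: List[Set]
    small_world: Optional[SmallWorldResult]
    settings: dict = field(default_factory=dict)


def compute_graph_metrics(g, seed: int = 0, n_nulls: int = 20) -> GraphMetrics:
    """Bundle of all node and network measures on one graph.

    ``g`` may be a directed functional graph or a plain graph; metrics run on
    the binarized symmetrized version.  Small-worldness is None when the graph
    cannot support the rewired null model.
    """
    h = _as_simple_graph(g)
    part = detect_communities(h, seed=seed)
    try:
        sw = small_world(h, n_nulls=n_nulls, seed=seed)
    except (NullModelError, ConfigError):
        sw = None
    n = h.number_of_nodes()
    return GraphMetrics(
        degree=degree(h),
        betweenness=betweenness(h) if n >= 3 else {v: 0.0 for v in h.nodes},
        density=density(h) if n >= 2 else float("nan"),
        n_nodes=n,
        n_links=h.number_of_edges(),
        global_efficiency=global_efficiency(h),
        modularity=modularity(h, part),
        partition=part,
        small_world=sw,
        settings={"seed": seed, "n_nulls": n_nulls, "community_algorithm": "greedy_modularity"},
    )
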