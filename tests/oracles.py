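"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (double loops, path enumeration,
closed-form mixing matrices) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def correlogram_brute(x, y, lags, delta_tau, normalization="product"):
    """O(Nx * Ny) double loop over all spike pairs, closed lag windows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    half = delta_tau / 2.0
    values = np.zeros(len(lags))
    for li, tau in enumerate(lags):
        c = 0
        for xs in x:
            for ys in y:
                if tau - half <= ys - xs <= tau + half:
                    c += 1
        values[li] = c
    if normalization == "product":
        return values / (len(x) * len(y))
    return values / np.sqrt(len(x) * len(y))


def synchrony_brute(x, y, tau_s):
    """O(N^2) nearest-neighbour scan, symmetrized."""

    def one_way(a, b):
        total = 0.0
        for s in a:
            dt = min(abs(s - t) for t in b)
            total += 1.0 / (1.0 + dt / tau_s)
        return total / len(a)

    return 0.5 * (one_way(x, y) + one_way(y, x))


def pearson_brute(u, v):
    """Direct textbook formula."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    du = u - u.mean()
    dv = v - v.mean()
    return float(np.sum(du * dv) / np.sqrt(np.sum(du**2) * np.sum(dv**2)))


def adjacency(g, nodes):
    a = np.zeros((len(nodes), len(nodes)))
    pos = {n: i for i, n in enumerate(nodes)}
    for u, v in g.edges:
        if u == v:
            continue
        a[pos[u], pos[v]] = 1
        a[pos[v], pos[u]] = 1
    return a


def degree_brute(g):
    nodes = sorted(g.nodes)
    a = adjacency(g, nodes)
    return {n: int(a[i].sum()) for i, n in enumerate(nodes)}


def density_brute(g):
    nodes = sorted(g.nodes)
    a = adjacency(g, nodes)
    n = len(nodes)
    return a.sum() / (n * (n - 1))


def shortest_paths_brute(g):
    """Hop-count distance matrix and shortest-path counts by path enumeration
    (breadth-first layer counting).  Suitable for <= 12 nodes."""
    nodes = sorted(g.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = adjacency(g, nodes)
    inf = float("inf")
    dist = np.full((n, n), inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                dist[i, j] = 1.0
    for k in range(n):  # Floyd-Warshall
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    # Count shortest paths by dynamic programming over distance layers.
    counts = np.zeros((n, n))
    for s in range(n):
        counts[s, s] = 1.0
        order = sorted(range(n), key=lambda v: dist[s, v])
        for v in order:
            if v == s or dist[s, v] == inf:
                continue
            counts[s, v] = sum(
                counts[s, u] for u in range(n) if a[u, v] and dist[s, u] + 1 == dist[s, v]
            )
    return nodes, dist, counts


def efficiency_brute(g):
    nodes, dist, _ = shortest_paths_brute(g)
    n = len(nodes)
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def betweenness_brute(g):
    """Per-node betweenness over unordered pairs, normalized by (n-1)(n-2),
    via explicit shortest-path counting."""
    nodes, dist, counts = shortest_paths_brute(g)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    if n < 3:
        return out
    for v in nodes:
        i = pos[v]
        acc = 0.0
        for a, b in combinations([u for u in nodes if u != v], 2):
            ia, ib = pos[a], pos[b]
            if not np.isfinite(dist[ia, ib]) or counts[ia, ib] == 0:
                continue
            # paths through v: d(a,v) + d(v,b) == d(a,b)
            if dist[ia, i] + dist[i, ib] == dist[ia, ib]:
                through = counts[ia, i] * counts[i, ib]
            else:
                through = 0.0
            acc += through / counts[ia, ib]
        out[v] = acc / ((n - 1) * (n - 2))
    return out


def modularity_brute(g, partition):
    """Newman degree-sum formulation: Q = sum_u [m_uu/m - (sum_{i in u} k_i / 2m)^2].

    Algebraically equal to the mixing-matrix formula but computed through
    intra-module edge counts and degree sums rather than the e_uv matrix.
    """
    mods = [set(m) for m in partition]
    edges = [(u, v) for u, v in g.edges if u != v]
    m = len(edges)
    if m == 0:
        return 0.0
    deg = degree_brute(g)
    q = 0.0
    for mod in mods:
        m_uu = sum(1 for u, v in edges if u in mod and v in mod)
        k_u = sum(deg[i] for i in mod)
        q += m_uu / m - (k_u / (2.0 * m)) ** 2
    return float(q)


def entropy_brute(probabilities):
    return float(-sum(p * np.log2(p) for p in probabilities if p > 0))
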