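"""Brute-force reference implementations for small graphs.

Independent of the package's graph routines: distances and path counts
come from exhaustive simple-path enumeration over permutations of
intermediate nodes, so they are only usable for graphs of ~7 nodes.
"""

from itertools import combinations, permutations

import numpy as np


def enumerate_shortest_paths(adj, s, t):
    """(shortest length, count, interior-node pass counts) for pair s-t."""
    n = adj.shape[0]
    others = [v for v in range(n) if v not in (s, t)]
    best = np.inf
    paths = []
    for k in range(len(others) + 1):
        for mid in permutations(others, k):
            nodes = (s, *mid, t)
            if all(adj[a, b] for a, b in zip(nodes, nodes[1:])):
                length = len(nodes) - 1
                if length < best:
                    best = length
                    paths = [nodes]
                elif length == best:
                    paths.append(nodes)
    through = np.zeros(n)
    for path in paths:
        for v in path[1:-1]:
            through[v] += 1
    return best, len(paths), through


def brute_force_measures(adj):
    """lambda, C, E, BC of a small binary graph by path enumeration."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        d, count, through = enumerate_shortest_paths(adj, s, t)
        dist[s, t] = dist[t, s] = d
        if count:
            bc += through / count
    off = dist[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    lam = finite.mean() if finite.size else np.nan

    clustering = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        links = sum(adj[a, b] for a, b in combinations(nbrs, 2))
        clustering[i] = links / (k * (k - 1) / 2)

    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(off) & (off > 0), 1.0 / off, 0.0)
    eff = inv.mean() if off.size else 0.0

    bc_norm = bc / ((n - 1) * (n - 2) / 2.0) if n > 2 else bc
    return {
        "lambda": float(lam),
        "clustering": float(clustering.mean()),
        "efficiency": float(eff),
        "betweenness": float(bc_norm.mean()),
        "nodal_betweenness": bc_norm,
        "nodal_clustering": clustering,
        "distances": dist,
    }


def random_connected_graph(rng, n):
    """Random connected binary graph: spanning tree + random extra edges."""
    adj = np.zeros((n, n))
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[rng.integers(0, i)]
        adj[order[i], j] = adj[j, order[i]] = 1
    for a, b in combinations(range(n), 2):
        if rng.random() < 0.3:
            adj[a, b] = adj[b, a] = 1
    return adj


def all_connected_graphs(n):
    """Every connected labeled graph on n nodes (n <= 5 is practical)."""
    pairs = list(combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = np.zeros((n, n))
        for idx, (a, b) in enumerate(pairs):
            if bits >> idx & 1:
                adj[a, b] = adj[b, a] = 1
        if _connected(adj):
            yield adj


def _connected(adj):
    n = adj.shape[0]
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in np.flatnonzero(adj[v]):
            if u not in seen:
                seen.add(int(u))
                stack.append(int(u))
    return len(seen) == n
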