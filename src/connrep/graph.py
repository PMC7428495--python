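"""Graph measures, hubs, modularity co-assignment, null normalization.

Measures follow the brain-connectivity-toolbox conventions: weighted
distances use edge lengths 1/w, weighted clustering the geometric-mean
(Onnela) form with weights rescaled by the network maximum, betweenness
the Brandes accumulation normalized by (P−1)(P−2)/2.  Global measures are
the characteristic path length λ (mean finite distance), the mean nodal
clustering C, the global efficiency E (mean of 1/d) and the mean nodal
betweenness BC; their normalized versions λ_n, C_n, E_n, BC_n divide by
the mean over 30 equivalent random networks that preserve the density
(binary) or the weight multiset (weighted).

Module structure comes from Newman's leading-eigenvector algorithm run
100 times with randomized node order; the fraction of realizations that
co-assign two nodes gives the probabilistic co-assignment matrix.
"""

from __future__ import annotations

import random as _py_random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

__all__ = [
    "NodalMeasures",
    "CoAssignmentMatrix",
    "HubSet",
    "is_weighted",
    "shortest_path_lengths",
    "characteristic_path_length",
    "clustering_coefficient",
    "efficiency",
    "betweenness",
    "global_measures",
    "nodal_measures",
    "hub_scores",
    "newman_coassignment",
    "equivalent_random_networks",
    "normalize",
    "normalized_global_measures",
    "GLOBAL_MEASURE_NAMES",
]

GLOBAL_MEASURE_NAMES = ("lambda", "clustering", "efficiency", "betweenness")

N_NULL_DEFAULT = 30
N_MODULARITY_REALIZATIONS = 100


@dataclass
class NodalMeasures:
    degree: np.ndarray  # binary degree or weighted strength
    path_length: np.ndarray  # mean finite distance per node (nan if isolated)
    clustering: np.ndarray
    efficiency: np.ndarray  # efficiency of each node's neighbor subgraph
    betweenness: np.ndarray


@dataclass
class CoAssignmentMatrix:
    matrix: np.ndarray  # P × P co-assignment probabilities, diagonal 1
    n_realizations: int


@dataclass
class HubSet:
    score: np.ndarray  # 0..4 per node
    is_hub: np.ndarray  # score >= 2


def _validate(network: np.ndarray) -> np.ndarray:
    w = np.asarray(network, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("network must be a square matrix")
    if (w < 0).any():
        raise ValueError("negative weights are not allowed")
    if not np.allclose(w, w.T):
        raise ValueError("network must be symmetric")
    return w


def is_weighted(network: np.ndarray) -> bool:
    """A network whose nonzero entries are not all 1 is treated as weighted."""
    w = np.asarray(network)
    nz = w[w != 0]
    return bool(nz.size) and not np.all(nz == 1.0)


def shortest_path_lengths(network: np.ndarray,
                          weighted: bool | None = None) -> np.ndarray:
    """All-pairs distances: hop counts for binary graphs, Dijkstra on edge
    lengths 1/w for weighted ones; unreachable pairs are ∞."""
    w = _validate(network)
    if weighted is None:
        weighted = is_weighted(w)
    if weighted:
        with np.errstate(divide="ignore"):
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
        return _csgraph_sp(csr_matrix(lengths), method="D", directed=False)
    return _csgraph_sp(csr_matrix(w), method="D", directed=False, unweighted=True)


def characteristic_path_length(distances: np.ndarray):
    """(global λ, nodal vector, number of unreachable ordered pairs).

    Infinite distances are excluded from the means (their count is
    reported) rather than substituted; a node with no finite distance gets
    a nan nodal value.
    """
    d = np.asarray(distances, dtype=float).copy()
    np.fill_diagonal(d, np.nan)
    finite = np.isfinite(d)
    n_inf = int((~finite).sum() - d.shape[0])  # exclude the nan diagonal
    if not finite.any():
        raise ValueError("no finite node pairs: graph has no edges")
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    nodal = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    global_ = float(np.mean(d[finite]))
    return global_, nodal, n_inf


def clustering_coefficient(network: np.ndarray,
                           weighted: bool | None = None) -> np.ndarray:
    """Nodal clustering: triangle density for binary graphs, the Onnela
    geometric-mean form for weighted ones (weights scaled by the max)."""
    w = _validate(network)
    if weighted is None:
        weighted = is_weighted(w)
    k = np.count_nonzero(w, axis=1).astype(float)
    denom = k * (k - 1)
    if weighted:
        mx = w.max()
        if mx == 0:
            return np.zeros(w.shape[0])
        m = np.cbrt(w / mx)
    else:
        m = w
    tri = np.diag(m @ m @ m)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def _pairwise_efficiency(distances: np.ndarray) -> float:
    inv = np.zeros_like(distances)
    finite = np.isfinite(distances) & (distances > 0)
    inv[finite] = 1.0 / distances[finite]
    np.fill_diagonal(inv, 0.0)
    p = distances.shape[0]
    if p < 2:
        return 0.0
    return float(inv.sum() / (p * (p - 1)))


def efficiency(network: np.ndarray, weighted: bool | None = None,
               nodal: bool = False):
    """Global efficiency (mean of 1/d over ordered pairs, 1/∞ = 0); with
    ``nodal=True`` also the efficiency of each node's neighbor subgraph."""
    w = _validate(network)
    if weighted is None:
        weighted = is_weighted(w)
    d = shortest_path_lengths(w, weighted)
    e_glob = _pairwise_efficiency(d)
    if not nodal:
        return e_glob
    p = w.shape[0]
    e_nodal = np.zeros(p)
    for i in range(p):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        e_nodal[i] = _pairwise_efficiency(shortest_path_lengths(sub, weighted))
    return e_glob, e_nodal


def _igraph_from_adjacency(w: np.ndarray):
    """(graph, edge weight array or None) from a dense symmetric matrix."""
    iu, ju = np.triu_indices(w.shape[0], k=1)
    nz = w[iu, ju] > 0
    edges = list(zip(iu[nz].tolist(), ju[nz].tolist()))
    g = ig.Graph(n=w.shape[0], edges=edges)
    weights = w[iu, ju][nz]
    return g, weights


def betweenness(network: np.ndarray,
                weighted: bool | None = None) -> np.ndarray:
    """Nodal betweenness centrality normalized by (P−1)(P−2)/2; weighted
    graphs use shortest paths on edge lengths 1/w."""
    w = _validate(network)
    if weighted is None:
        weighted = is_weighted(w)
    p = w.shape[0]
    if p < 3:
        return np.zeros(p)
    g, ew = _igraph_from_adjacency(w)
    if ew.size == 0:
        return np.zeros(p)
    bc = np.asarray(
        g.betweenness(weights=(1.0 / ew) if weighted else None), dtype=float
    )
    return bc / ((p - 1) * (p - 2) / 2.0)


def global_measures(network: np.ndarray,
                    weighted: bool | None = None) -> dict[str, float]:
    """λ, C, E, BC of one network (BC = mean of normalized nodal values)."""
    w = _validate(network)
    if weighted is None:
        weighted = is_weighted(w)
    d = shortest_path_lengths(w, weighted)
    lam, _, _ = characteristic_path_length(d)
    return {
        "lambda": lam,
        "clustering": float(clustering_coefficient(w, weighted).mean()),
        "efficiency": _pairwise_efficiency(d),
        "betweenness": float(betweenness(w, weighted).mean()),
    }


def nodal_measures(network: np.ndarray, weighted: bool | None = None,
                   include_efficiency: bool = True) -> NodalMeasures:
    """Per-node degree/strength, path length, clustering, neighbor-subgraph
    efficiency and betweenness.  The efficiency loop is the slow part; pass
    ``include_efficiency=False`` (zeros returned) when only the four
    hub-score inputs are needed."""
    w = _validate(network)
    if weighted is None:
        weighted = is_weighted(w)
    d = shortest_path_lengths(w, weighted)
    _, nodal_pl, _ = characteristic_path_length(d)
    if include_efficiency:
        _, e_nodal = efficiency(w, weighted, nodal=True)
    else:
        e_nodal = np.zeros(w.shape[0])
    return NodalMeasures(
        degree=w.sum(axis=1) if weighted else np.count_nonzero(w, axis=1).astype(float),
        path_length=nodal_pl,
        clustering=clustering_coefficient(w, weighted),
        efficiency=e_nodal,
        betweenness=betweenness(w, weighted),
    )


def _top_indices(values: np.ndarray, m: int, lowest: bool = False) -> np.ndarray:
    """Deterministic top-m selection; ties broken by smaller node index.

    nan values sort last in both directions (a node with no finite path
    length never counts as 'shortest path length')."""
    v = np.asarray(values, dtype=float).copy()
    v[np.isnan(v)] = np.inf if lowest else -np.inf
    key = v if lowest else -v
    order = np.lexsort((np.arange(v.size), key))
    return order[:m]


def hub_scores(nodal: NodalMeasures) -> HubSet:
    """Hub score 0–4: membership in the top round(0.2·P) by degree and
    betweenness, the bottom round(0.2·P) by path length and clustering;
    a node is a hub when the score is at least 2."""
    p = nodal.degree.size
    m = int(np.floor(0.2 * p + 0.5))
    score = np.zeros(p, dtype=int)
    for values, lowest in (
        (nodal.degree, False),
        (nodal.path_length, True),
        (nodal.clustering, True),
        (nodal.betweenness, False),
    ):
        score[_top_indices(values, m, lowest)] += 1
    return HubSet(score=score, is_hub=score >= 2)


def newman_coassignment(
    network: np.ndarray,
    n_realizations: int = N_MODULARITY_REALIZATIONS,
    seed: int | None = None,
):
    """Probabilistic module co-assignment over repeated Newman runs.

    Each realization permutes the node order, runs leading-eigenvector
    modularity maximization, and maps the membership back; P(i, j) is the
    fraction of realizations placing i and j in the same module.  Returns
    the co-assignment matrix and the best (highest-modularity) partition,
    labels contiguous from 1.
    """
    w = _validate(network)
    p = w.shape[0]
    if not (w > 0).any():
        raise ValueError("cannot find modules in an empty network")
    rng = np.random.default_rng(seed)
    weighted = is_weighted(w)
    co = np.zeros((p, p))
    best_q, best_membership = -np.inf, None
    for _ in range(n_realizations):
        perm = rng.permutation(p)
        wp = w[np.ix_(perm, perm)]
        g, ew = _igraph_from_adjacency(wp)
        # igraph draws ARPACK start vectors from Python's random module;
        # seeding it per realization keeps runs reproducible, and a reseeded
        # retry rides out occasional ARPACK non-convergence
        cl = None
        for _attempt in range(5):
            _py_random.seed(int(rng.integers(0, 2**31)))
            try:
                cl = g.community_leading_eigenvector(
                    weights=ew if weighted else None
                )
                break
            except ig.InternalError:
                continue
        if cl is None:
            raise RuntimeError("leading-eigenvector ARPACK failed repeatedly")
        membership = np.empty(p, dtype=int)
        membership[perm] = np.asarray(cl.membership)
        co += membership[:, None] == membership[None, :]
        q = cl.modularity
        if q > best_q:
            best_q, best_membership = q, membership
    co /= n_realizations
    np.fill_diagonal(co, 1.0)
    # relabel best partition contiguously from 1 in order of first appearance
    _, labels = np.unique(best_membership, return_inverse=True)
    return CoAssignmentMatrix(co, n_realizations), labels + 1


def equivalent_random_networks(
    network: np.ndarray,
    n_null: int = N_NULL_DEFAULT,
    seed: int | None = None,
    weighted: bool | None = None,
) -> list[np.ndarray]:
    """Random networks matched on size and density / weight distribution.

    Binary: the same number of edges placed uniformly at random over node
    pairs.  Weighted: the upper-triangle weight multiset randomly permuted
    over all node pairs.  No self-loops; reproducible from ``seed``.
    """
    w = _validate(network)
    if weighted is None:
        weighted = is_weighted(w)
    p = w.shape[0]
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(p, k=1)
    vals = w[iu, ju]
    nulls = []
    for _ in range(n_null):
        null = np.zeros((p, p))
        if weighted:
            null[iu, ju] = rng.permutation(vals)
        else:
            k = int(np.count_nonzero(vals))
            sel = rng.choice(vals.size, size=k, replace=False)
            null[iu[sel], ju[sel]] = 1.0
        null += null.T
        nulls.append(null)
    return nulls


def normalize(value: float, null_values) -> float:
    """Measure divided by the mean of its null-network values."""
    mean = float(np.mean(null_values))
    if mean == 0:
        raise ValueError("null mean is zero; normalized measure undefined")
    return float(value) / mean


def normalized_global_measures(
    network: np.ndarray,
    n_null: int = N_NULL_DEFAULT,
    seed: int | None = None,
    weighted: bool | None = None,
) -> dict[str, dict[str, float]]:
    """Raw and normalized λ, C, E, BC with the null-distribution summary.

    Returns ``{measure: {value, normalized, null_mean, null_sd}}``.
    """
    w = _validate(network)
    if weighted is None:
        weighted = is_weighted(w)
    own = global_measures(w, weighted)
    nulls = equivalent_random_networks(w, n_null, seed, weighted)
    null_vals = {name: [] for name in GLOBAL_MEASURE_NAMES}
    for null in nulls:
        gm = global_measures(null, weighted)
        for name in GLOBAL_MEASURE_NAMES:
            null_vals[name].append(gm[name])
    out = {}
    for name in GLOBAL_MEASURE_NAMES:
        arr = np.asarray(null_vals[name])
        out[name] = {
            "value": own[name],
            "normalized": normalize(own[name], arr),
            "null_mean": float(arr.mean()),
            "null_sd": float(arr.std(ddof=1)),
        }
    return out
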