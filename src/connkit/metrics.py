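"""Topological properties of binary and weighted connectomes.

Distances follow the reciprocal-weight convention: a stronger edge (higher FA,
more streamlines, longer mean tract) is a shorter step, length = 1/weight.
Global efficiency is the mean inverse shortest-path distance over ordered node
pairs (unreachable pairs contribute zero); the characteristic path length is
the mean distance over *reachable* pairs, reported together with the fraction
of unreachable pairs so disconnected subjects stay comparable.

Small-world indices gamma (normalized clustering), lambda (normalized path
length) and sigma = gamma/lambda are computed against degree-preserving
Maslov-Sneppen rewired null networks, weights travelling with the rewired
edges.

Shortest paths are delegated to scipy's Dijkstra; betweenness and weighted
(Onnela) clustering to networkx.  :func:`floyd_warshall_reference` is a
straightforward dense dynamic-programming all-pairs solver kept as an
independent cross-check of the Dijkstra route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .core import ConnectomeMatrix, StudyCohort, ValidationError
from .backbone import BackboneMask, apply_mask, binarize

__all__ = [
    "DistanceMatrix",
    "GlobalMetrics",
    "NullModelConfig",
    "edge_lengths",
    "shortest_paths",
    "floyd_warshall_reference",
    "global_efficiency",
    "characteristic_path_length",
    "nodal_efficiency",
    "degree_centrality",
    "betweenness_centrality",
    "clustering_coefficient",
    "local_efficiency",
    "rewire_preserving_degree",
    "small_world_indices",
    "compute_all",
]


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path distances; ``inf`` marks unreachable pairs."""

    d: np.ndarray
    weighting: str = "binary"

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class GlobalMetrics:
    global_efficiency: float
    shortest_path_length: float
    local_efficiency: float
    clustering_coefficient: float
    unreachable_fraction: float
    gamma: float = np.nan
    lambda_: float = np.nan
    sigma: float = np.nan


@dataclass(frozen=True)
class NullModelConfig:
    """Degree-preserving rewiring nulls for the small-world indices."""

    n_null: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValidationError("n_null must be >= 1")


# ---------------------------------------------------------------------------
# Distances and efficiency
# ---------------------------------------------------------------------------

def edge_lengths(m: ConnectomeMatrix, *, fl_as_cost: bool = False) -> np.ndarray:
    """Length matrix: 1/w on edges, ``inf`` where w = 0 (unit lengths for the
    binary weighting by construction).

    ``fl_as_cost=True`` treats FL weights as path cost directly (longer mean
    tract = longer step) instead of the default reciprocal convention.
    """
    w = m.values
    lengths = np.full_like(w, np.inf, dtype=float)
    on = w > 0
    if fl_as_cost and m.weighting == "FL":
        lengths[on] = w[on]
    else:
        lengths[on] = 1.0 / w[on]
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_paths(lengths: np.ndarray, weighting: str = "binary") -> DistanceMatrix:
    """Exact all-pairs shortest-path distances (Dijkstra on the finite edges)."""
    lengths = np.asarray(lengths, dtype=float)
    finite = np.isfinite(lengths) & (lengths > 0)
    if np.any(lengths[finite] < 0):
        raise ValidationError("edge lengths must be nonnegative")
    n = lengths.shape[0]
    graph = csr_matrix((lengths[finite], np.nonzero(finite)), shape=(n, n))
    d = _csgraph_shortest_path(graph, method="D", directed=False)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, weighting=weighting)


def floyd_warshall_reference(lengths: np.ndarray) -> np.ndarray:
    """Independent dense all-pairs oracle: classic Floyd-Warshall relaxation."""
    d = np.array(lengths, dtype=float)
    d[d == 0] = np.inf
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def global_efficiency(d: DistanceMatrix) -> float:
    """Mean inverse distance over ordered pairs; unreachable pairs add 0."""
    n = d.n
    if n < 2:
        raise ValidationError("global efficiency needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d.d)
    reach = off & np.isfinite(d.d) & (d.d > 0)
    inv[reach] = 1.0 / d.d[reach]
    return float(inv[off].sum() / (n * (n - 1)))


def characteristic_path_length(d: DistanceMatrix, *,
                               mode: str = "reachable_mean") -> tuple[float, float]:
    """(L_p, unreachable_fraction).

    ``mode="reachable_mean"`` (default): mean distance over reachable ordered
    pairs, ``inf`` if none are reachable.  ``mode="harmonic"``: harmonic mean
    over all ordered pairs (the reciprocal of global efficiency), which stays
    finite for disconnected graphs.
    """
    n = d.n
    if n < 2:
        raise ValidationError("path length needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d.d)
    unreachable = 1.0 - finite.sum() / (n * (n - 1))
    if mode == "harmonic":
        eg = global_efficiency(d)
        return (np.inf if eg == 0 else 1.0 / eg), float(unreachable)
    if mode != "reachable_mean":
        raise ValidationError(f"unknown path-length mode {mode!r}")
    if not finite.any():
        return np.inf, 1.0
    return float(d.d[finite].mean()), float(unreachable)


def nodal_efficiency(d: DistanceMatrix, i: int | None = None):
    """E_nodal(i) = mean inverse distance from node i to every other node.

    With ``i=None`` returns the full per-node vector.
    """
    n = d.n
    if n < 2:
        raise ValidationError("nodal efficiency needs at least 2 nodes")
    inv = np.zeros_like(d.d)
    off = ~np.eye(n, dtype=bool)
    reach = off & np.isfinite(d.d) & (d.d > 0)
    inv[reach] = 1.0 / d.d[reach]
    vec = inv.sum(axis=1) / (n - 1)
    if i is None:
        return vec
    if not (0 <= i < n):
        raise ValidationError(f"node index {i} out of range")
    return float(vec[i])


def nodal_shortest_path_length(d: DistanceMatrix) -> np.ndarray:
    """Per-node mean distance to the reachable other nodes (inf if isolated)."""
    n = d.n
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d.d)
    out = np.full(n, np.inf)
    counts = finite.sum(axis=1)
    ok = counts > 0
    sums = np.where(finite, d.d, 0.0).sum(axis=1)
    out[ok] = sums[ok] / counts[ok]
    return out


# ---------------------------------------------------------------------------
# Centrality and clustering
# ---------------------------------------------------------------------------

def degree_centrality(m: ConnectomeMatrix, i: int | None = None):
    """Binary: incident edge count. Weighted: node strength (summed weights)."""
    vec = m.values.sum(axis=1)
    if i is None:
        return vec
    if not (0 <= i < m.n_nodes):
        raise ValidationError(f"node index {i} out of range")
    return float(vec[i])


def _to_length_graph(m: ConnectomeMatrix) -> nx.Graph:
    lengths = edge_lengths(m)
    g = nx.Graph()
    g.add_nodes_from(range(m.n_nodes))
    ii, jj = np.nonzero(np.triu(m.values, 1))
    g.add_weighted_edges_from(
        (int(a), int(b), float(lengths[a, b])) for a, b in zip(ii, jj))
    return g


def betweenness_centrality(m: ConnectomeMatrix) -> np.ndarray:
    """Fraction of all-pairs shortest paths (by edge length) through each node,
    normalized by (N-1)(N-2)/2; equal-length multiplicity shared fractionally."""
    g = _to_length_graph(m)
    bc = nx.betweenness_centrality(g, weight="weight", normalized=True)
    return np.array([bc[i] for i in range(m.n_nodes)])


def clustering_coefficient(m: ConnectomeMatrix) -> tuple[np.ndarray, float]:
    """Per-node clustering and its mean C_p.

    Binary: triangle density among neighbors.  Weighted: Onnela geometric-mean
    form with weights scaled by the maximum weight.  Degree < 2 gives 0.
    """
    v = m.values
    n = m.n_nodes
    if m.weighting == "binary":
        a = (v > 0).astype(float)
        deg = a.sum(axis=1)
        tri = np.diag(a @ a @ a) / 2.0
        denom = deg * (deg - 1) / 2.0
        c = np.zeros(n)
        ok = denom > 0
        c[ok] = tri[ok] / denom[ok]
    else:
        g = nx.from_numpy_array(v)
        cdict = nx.clustering(g, weight="weight")
        c = np.array([cdict[i] for i in range(n)])
    return c, float(c.mean()) if n else 0.0


def local_efficiency(m: ConnectomeMatrix) -> tuple[np.ndarray, float]:
    """E_loc(i) = global efficiency of the subgraph induced on i's neighbors
    (0 for degree < 2), and the mean over nodes."""
    v = m.values
    n = m.n_nodes
    out = np.zeros(n)
    adj = v > 0
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        if len(nbrs) < 2:
            continue
        sub = v[np.ix_(nbrs, nbrs)]
        lengths = np.full_like(sub, np.inf)
        on = sub > 0
        lengths[on] = 1.0 / sub[on]
        np.fill_diagonal(lengths, 0.0)
        d = shortest_paths(lengths, m.weighting)
        out[i] = global_efficiency(d)
    return out, float(out.mean()) if n else 0.0


# ---------------------------------------------------------------------------
# Null models and small-world indices
# ---------------------------------------------------------------------------

def rewire_preserving_degree(m: ConnectomeMatrix,
                             config: NullModelConfig) -> ConnectomeMatrix:
    """Maslov-Sneppen double-edge swaps: the binary degree sequence is exactly
    preserved and edge weights travel with the rewired edges.

    Attempts ``swaps_per_edge * E`` swaps; a graph with < 2 edges is returned
    unchanged.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    v = m.values.copy()
    edges = [tuple(e) for e in np.argwhere(np.triu(v, 1) > 0)]
    n_edges = len(edges)
    if n_edges < 2:
        return m.copy_with(v)
    adj = v > 0
    attempts = config.swaps_per_edge * n_edges
    for _ in range(attempts):
        k1, k2 = rng.integers(0, n_edges, size=2)
        if k1 == k2:
            continue
        (a, b), (c, d) = edges[k1], edges[k2]
        # swap to (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        w1, w2 = v[a, b], v[c, d]
        v[a, b] = v[b, a] = 0.0
        v[c, d] = v[d, c] = 0.0
        v[a, d] = v[d, a] = w1
        v[c, b] = v[b, c] = w2
        adj[a, b] = adj[b, a] = adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = adj[c, b] = adj[b, c] = True
        edges[k1] = (min(a, d), max(a, d))
        edges[k2] = (min(c, b), max(c, b))
    return m.copy_with(v)


def small_world_indices(m: ConnectomeMatrix,
                        config: NullModelConfig) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against ``n_null`` degree-preserving nulls.

    gamma = C_p / mean(C_p of nulls); lambda = L_p / mean(L_p of nulls);
    sigma = gamma / lambda.  A disconnected null contributes its
    reachable-pair mean path length.
    """
    _, cp = clustering_coefficient(m)
    d = shortest_paths(edge_lengths(m), m.weighting)
    lp, _ = characteristic_path_length(d)
    cps, lps = [], []
    for k in range(config.n_null):
        null_cfg = NullModelConfig(n_null=1, swaps_per_edge=config.swaps_per_edge,
                                   seed=int(np.random.SeedSequence(
                                       [config.seed, k]).generate_state(1)[0] % (2**31)))
        null = rewire_preserving_degree(m, null_cfg)
        _, c_null = clustering_coefficient(null)
        d_null = shortest_paths(edge_lengths(null), null.weighting)
        l_null, _ = characteristic_path_length(d_null)
        cps.append(c_null)
        lps.append(l_null)
    mean_c = float(np.mean(cps))
    mean_l = float(np.mean(lps))
    gamma = cp / mean_c if mean_c > 0 else np.nan
    lam = lp / mean_l if mean_l > 0 else np.nan
    sigma = gamma / lam
    return gamma, lam, sigma


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

def compute_all(cohort: StudyCohort, mask: BackboneMask | None = None,
                null_config: NullModelConfig | None = None,
                weightings: tuple[str, ...] | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global and nodal metrics per subject per weighting.

    Returns ``(global_df, nodal_df)``: tidy frames keyed by
    (subject, group, weighting[, node], metric).  Small-world indices are
    computed only when ``null_config`` is given (they dominate run time).
    """
    weightings = weightings or cohort.weightings
    node_ids = cohort.atlas.retained_ids
    grows, nrows = [], []
    for s in cohort.subjects:
        for w in weightings:
            mat = s.matrices[w]
            if mask is not None:
                mat = apply_mask(mat, mask)
            if w == "binary":
                mat = binarize(mat)
            d = shortest_paths(edge_lengths(mat), w)
            eg = global_efficiency(d)
            lp, unreach = characteristic_path_length(d)
            cvec, cp = clustering_coefficient(mat)
            evec, eloc = local_efficiency(mat)
            row = {
                "subject": s.subject_id, "group": s.group, "weighting": w,
                "global_efficiency": eg, "shortest_path_length": lp,
                "local_efficiency": eloc, "clustering_coefficient": cp,
                "unreachable_fraction": unreach,
            }
            if null_config is not None:
                gamma, lam, sigma = small_world_indices(mat, null_config)
                row.update(gamma=gamma, lambda_=lam, sigma=sigma)
            grows.append(row)

            ne = nodal_efficiency(d)
            dc = degree_centrality(mat)
            bc = betweenness_centrality(mat)
            nlp = nodal_shortest_path_length(d)
            for k, nid in enumerate(node_ids):
                nrows.append({
                    "subject": s.subject_id, "group": s.group, "weighting": w,
                    "node": nid,
                    "nodal_efficiency": ne[k],
                    "degree_centrality": dc[k],
                    "betweenness_centrality": bc[k],
                    "clustering_coefficient": cvec[k],
                    "nodal_shortest_path_length": nlp[k],
                })
    return pd.DataFrame(grows), pd.DataFrame(nrows)
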