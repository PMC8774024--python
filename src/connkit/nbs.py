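"""Edge-wise permutation ANOVA with network-based family-wise error control.

Single-edge tests over hundreds of connections need multiple-comparison
control; the network-based statistic (NBS) gains power by scoring *connected
components* of suprathreshold edges instead of single edges.  Procedure:

1. a one-way F statistic is computed at every backbone edge across subjects;
2. edges with F above a primary component-forming threshold (the F quantile
   at ``primary_alpha``) are kept, and their connected components scored by
   extent (edge count) or intensity (summed excess F);
3. group labels are permuted ``n_perm`` times preserving group sizes; each
   permutation contributes its maximal component score to the null
   distribution;
4. each observed component gets p_fwe = (1 + #{null >= observed}) /
   (n_perm + 1) — the add-one estimator, so p is never zero.

The permutation F sweep is vectorized over edges and permutations: the total
sum of squares per edge is permutation-invariant, so each permutation only
needs group sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import StudyCohort, ValidationError
from .backbone import BackboneMask

__all__ = ["NBSConfig", "Component", "NBSResult", "edgewise_f",
           "suprathreshold_components", "nbs_test"]

#: Sentinel F for degenerate edges (between-group variance > 0 but zero
#: within-group variance).
F_SENTINEL = 1e12


@dataclass(frozen=True)
class NBSConfig:
    n_perm: int = 5000
    primary_alpha: float = 0.01
    component_stat: str = "extent"   # or "intensity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if not (0.0 < self.primary_alpha < 1.0):
            raise ValidationError("primary_alpha must lie in (0, 1)")
        if self.component_stat not in ("extent", "intensity"):
            raise ValidationError(
                f"unknown component_stat {self.component_stat!r}")


@dataclass
class Component:
    edges: list[tuple[str, str]]
    stat: float
    p_fwe: float = np.nan


@dataclass
class NBSResult:
    components: list[Component]
    f_threshold: float
    edge_index: list[tuple[str, str]]
    f_stats: np.ndarray
    config: NBSConfig
    weighting: str
    degenerate_edges: list[tuple[str, str]] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[Component]:
        return [c for c in self.components if c.p_fwe < alpha]

    def to_dict(self) -> dict:
        return {
            "weighting": self.weighting,
            "f_threshold": self.f_threshold,
            "n_perm": self.config.n_perm,
            "primary_alpha": self.config.primary_alpha,
            "component_stat": self.config.component_stat,
            "components": [
                {"edges": [list(e) for e in c.edges],
                 "stat": c.stat, "p_fwe": c.p_fwe}
                for c in self.components
            ],
        }


# ---------------------------------------------------------------------------
# Edge-wise F
# ---------------------------------------------------------------------------

def _group_layout(labels: np.ndarray) -> tuple[list[str], list[np.ndarray]]:
    groups = list(dict.fromkeys(labels))
    idx = [np.nonzero(labels == g)[0] for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for g, ix in zip(groups, idx):
        if len(ix) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
    return groups, idx


def _f_from_values(values: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Classical one-way F per column of ``values`` (subjects x edges)."""
    n_total = values.shape[0]
    k = len(group_idx)
    grand = values.mean(axis=0)
    sst = ((values - grand) ** 2).sum(axis=0)
    ssb = np.zeros(values.shape[1])
    for ix in group_idx:
        ssb += len(ix) * (values[ix].mean(axis=0) - grand) ** 2
    ssw = sst - ssb
    dfb, dfw = k - 1, n_total - k
    f = np.zeros(values.shape[1])
    ok = ssw > 1e-300 * np.maximum(sst, 1.0)
    f[ok] = (ssb[ok] / dfb) / (ssw[ok] / dfw)
    degenerate = (~ok) & (ssb > 0)
    f[degenerate] = F_SENTINEL
    # ssb == 0 and ssw == 0 (all values equal): F = 0 already
    return f


def edgewise_f(cohort: StudyCohort, weighting: str,
               mask: BackboneMask) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """One-way F per backbone edge; returns (F vector, edge id list)."""
    values, edge_ids = _edge_value_matrix(cohort, weighting, mask)
    _, group_idx = _group_layout(cohort.group_labels())
    return _f_from_values(values, group_idx), edge_ids


def _edge_value_matrix(cohort: StudyCohort, weighting: str,
                       mask: BackboneMask) -> tuple[np.ndarray, list[tuple[str, str]]]:
    ii, jj = np.nonzero(np.triu(mask.mask, 1))
    if len(ii) == 0:
        raise ValidationError("backbone mask retains no edges")
    stack = cohort.stack(weighting)
    values = stack[:, ii, jj]
    ids = cohort.atlas.retained_ids
    edge_ids = [(ids[a], ids[b]) for a, b in zip(ii, jj)]
    return values, edge_ids


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        while p != x:
            self.parent[x] = p = self.parent.setdefault(p, p)
            x = p
            p = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def suprathreshold_components(f_stats: np.ndarray,
                              threshold: float,
                              edge_index: list[tuple[str, str]],
                              component_stat: str = "extent") -> list[Component]:
    """Connected components of the edges with F > threshold.

    The result is independent of edge ordering: components are canonicalized
    by sorted edge lists.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    keep = np.nonzero(f_stats > threshold)[0]
    if len(keep) == 0:
        return []
    uf = _UnionFind()
    for k in keep:
        a, b = edge_index[k]
        uf.union(a, b)
    buckets: dict = {}
    for k in keep:
        root = uf.find(edge_index[k][0])
        buckets.setdefault(root, []).append(k)
    comps = []
    for ks in buckets.values():
        edges = sorted(tuple(sorted(edge_index[k])) for k in ks)
        if component_stat == "extent":
            stat = float(len(ks))
        else:
            stat = float(sum(f_stats[k] - threshold for k in ks))
        comps.append(Component(edges=[tuple(e) for e in edges], stat=stat))
    comps.sort(key=lambda c: (-c.stat, c.edges))
    return comps


def _max_component_stat(f_row: np.ndarray, threshold: float,
                        edge_nodes: np.ndarray,
                        component_stat: str) -> float:
    """Max component score for one permutation (integer-node union-find)."""
    keep = np.nonzero(f_row > threshold)[0]
    if len(keep) == 0:
        return 0.0
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in keep:
        a, b = edge_nodes[k]
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    scores: dict[int, float] = {}
    for k in keep:
        root = find(int(edge_nodes[k][0]))
        inc = 1.0 if component_stat == "extent" else float(f_row[k] - threshold)
        scores[root] = scores.get(root, 0.0) + inc
    return max(scores.values())


# ---------------------------------------------------------------------------
# Full test
# ---------------------------------------------------------------------------

def nbs_test(cohort: StudyCohort, weighting: str, mask: BackboneMask,
             config: NBSConfig) -> NBSResult:
    """Network-based permutation ANOVA on one weighting.

    Deterministic under ``config.seed``; the primary threshold is the
    F(k-1, n-k) upper quantile at ``primary_alpha``.
    """
    labels = cohort.group_labels()
    groups, group_idx = _group_layout(labels)
    values, edge_ids = _edge_value_matrix(cohort, weighting, mask)
    n, n_edges = values.shape
    k = len(groups)
    f_threshold = float(stats.f.ppf(1 - config.primary_alpha, k - 1, n - k))

    f_obs = _f_from_values(values, group_idx)
    comps = suprathreshold_components(f_obs, f_threshold, edge_ids,
                                      config.component_stat)

    # integer node labels for the fast per-permutation union-find
    node_pos = {nid: p for p, nid in enumerate(cohort.atlas.retained_ids)}
    edge_nodes = np.array([(node_pos[a], node_pos[b]) for a, b in edge_ids])

    rng = np.random.default_rng(config.seed)
    perms = np.array([rng.permutation(n) for _ in range(config.n_perm)])
    # group-sum based F for all permutations at once
    sizes = np.array([len(ix) for ix in group_idx])
    bounds = np.cumsum(sizes)[:-1]
    grand = values.mean(axis=0)
    sst = ((values - grand) ** 2).sum(axis=0)
    dfb, dfw = k - 1, n - k

    null_max = np.zeros(config.n_perm)
    # chunk the permutations to bound memory (P x n x E floats)
    chunk = max(1, int(2e7 // max(n * n_edges, 1)))
    for start in range(0, config.n_perm, chunk):
        p = perms[start:start + chunk]
        permuted = values[p]                       # (c, n, E)
        parts = np.split(permuted, bounds, axis=1)
        ssb = np.zeros((p.shape[0], n_edges))
        for part, sz in zip(parts, sizes):
            ssb += sz * (part.mean(axis=1) - grand) ** 2
        ssw = sst - ssb
        ok = ssw > 1e-300 * np.maximum(sst, 1.0)
        f_perm = np.zeros_like(ssb)
        f_perm[ok] = (ssb[ok] / dfb) / (ssw[ok] / dfw)
        f_perm[(~ok) & (ssb > 0)] = F_SENTINEL
        for r in range(f_perm.shape[0]):
            null_max[start + r] = _max_component_stat(
                f_perm[r], f_threshold, edge_nodes, config.component_stat)

    for c in comps:
        c.p_fwe = float((1 + np.sum(null_max >= c.stat)) / (config.n_perm + 1))

    degenerate = [edge_ids[k2] for k2 in np.nonzero(f_obs >= F_SENTINEL)[0]]
    return NBSResult(components=comps, f_threshold=f_threshold,
                     edge_index=edge_ids, f_stats=f_obs, config=config,
                     weighting=weighting, degenerate_edges=degenerate)
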