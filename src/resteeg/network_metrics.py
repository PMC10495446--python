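"""Proportional thresholding and binary graph measures.

Connectivity matrices are binarized by keeping the strongest fraction of
the n(n-1)/2 unordered pairs (default 20 %). Metrics: nodal degree and
clustering, global clustering (mean nodal), global efficiency (mean inverse
shortest path, unreachable pairs contribute 0), and smallworldness
sigma = (C/C_null) / (L/L_null) against degree-preserving rewired nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix


@dataclass
class BinaryGraph:
    adjacency: np.ndarray          # (n, n) symmetric 0/1, zero diagonal
    density: float                 # achieved edge density
    threshold: float               # smallest kept connection value

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class GraphMetrics:
    degree: np.ndarray
    clustering: np.ndarray
    global_clustering: float
    global_efficiency: float
    smallworldness: float
    n_null: int = 0
    null_seed: int = 0


def binarize_proportional(M: ConnectivityMatrix | np.ndarray,
                          density: float = 0.2) -> BinaryGraph:
    """Keep the top ``ceil(density * P)`` upper-triangle entries by value
    (P = n(n-1)/2); ties at the cutoff broken by (row, col) lexical order.
    Negative entries rank below positive ones (value order, no absolute)."""
    vals = M.values if isinstance(M, ConnectivityMatrix) else np.asarray(M, float)
    n = vals.shape[0]
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    iu, ju = np.triu_indices(n, k=1)
    v = vals[iu, ju]
    if np.ptp(v) == 0:
        raise ValueError("all connection values equal; proportional threshold "
                         "undefined")
    k = int(np.ceil(density * len(v)))
    # sort by value desc, then row asc, then col asc (deterministic ties)
    order = np.lexsort((ju, iu, -v))
    sel = order[:k]
    adj = np.zeros((n, n), dtype=int)
    adj[iu[sel], ju[sel]] = 1
    adj = adj + adj.T
    return BinaryGraph(adjacency=adj, density=k / len(v),
                       threshold=float(v[sel].min()))


def local_metrics(g: BinaryGraph) -> tuple[np.ndarray, np.ndarray]:
    """Nodal degree (row sum) and clustering 2 t_i / (k_i (k_i - 1))."""
    a = g.adjacency
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1)
    clust = np.where(denom > 0, 2 * tri / np.where(denom > 0, denom, 1), 0.0)
    return deg.astype(int), clust


def global_metrics(g: BinaryGraph) -> tuple[float, float]:
    """Global clustering (mean nodal) and global efficiency (mean inverse
    BFS distance over unordered pairs; unreachable pairs contribute 0)."""
    _, clust = local_metrics(g)
    d = shortest_path(g.adjacency, method="D", unweighted=True)
    iu = np.triu_indices(g.n_nodes, k=1)
    dv = d[iu]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dv) & (dv > 0), 1.0 / dv, 0.0)
    return float(clust.mean()), float(inv.mean())


def _largest_component(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    seen = np.zeros(n, bool)
    best: np.ndarray | None = None
    for start in range(n):
        if seen[start]:
            continue
        comp = [start]
        seen[start] = True
        stack = [start]
        while stack:
            u = stack.pop()
            for v in np.nonzero(a[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    comp.append(v)
                    stack.append(v)
        if best is None or len(comp) > len(best):
            best = np.array(comp)
    return best


def _char_path_length(a: np.ndarray) -> float:
    comp = _largest_component(a)
    sub = a[np.ix_(comp, comp)]
    d = shortest_path(sub, method="D", unweighted=True)
    iu = np.triu_indices(len(comp), k=1)
    dv = d[iu]
    dv = dv[np.isfinite(dv)]
    return float(dv.mean())


def _rewire(a: np.ndarray, rng: np.random.Generator,
            attempts_per_edge: int = 20) -> np.ndarray:
    """Degree-preserving double-edge swaps; ``attempts_per_edge * |E|``
    attempted swaps."""
    a = a.copy()
    iu, ju = np.nonzero(np.triu(a, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    n_attempts = attempts_per_edge * len(edges)
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, len(edges), size=2)
        if e1 == e2:
            continue
        (u, v), (x, y) = edges[e1], edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        # swap to (u, x), (v, y)
        if len({u, v, x, y}) < 4:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = (min(u, x), max(u, x))
        edges[e2] = (min(v, y), max(v, y))
    return a


def smallworldness(g: BinaryGraph, n_null: int = 10, seed: int = 0,
                   min_coverage: float = 0.9) -> float:
    """Humphries-Gurney sigma = (C/C_null) / (L/L_null) with C the global
    clustering and L the characteristic path length of the largest component,
    against ``n_null`` degree-preserving rewired graphs."""
    a = g.adjacency
    comp = _largest_component(a)
    if len(comp) < min_coverage * g.n_nodes:
        raise ValueError(
            f"largest component covers only {len(comp)}/{g.n_nodes} nodes; "
            "increase the binarization density")
    C, _ = global_metrics(g)
    L = _char_path_length(a)
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for _ in range(n_null):
        r = _rewire(a, rng)
        Cn, _ = global_metrics(BinaryGraph(r, g.density, g.threshold))
        c_null.append(Cn)
        l_null.append(_char_path_length(r))
    c0, l0 = float(np.mean(c_null)), float(np.mean(l_null))
    if c0 <= 0 or l0 <= 0:
        raise ValueError("degenerate null model (zero clustering or length)")
    return float((C / c0) / (L / l0))


def compute_graph_metrics(M: ConnectivityMatrix | np.ndarray,
                          density: float = 0.2, n_null: int = 10,
                          seed: int = 0) -> GraphMetrics:
    g = binarize_proportional(M, density)
    deg, clust = local_metrics(g)
    gc, ge = global_metrics(g)
    sw = smallworldness(g, n_null=n_null, seed=seed)
    return GraphMetrics(degree=deg, clustering=clust, global_clustering=gc,
                        global_efficiency=ge, smallworldness=sw,
                        n_null=n_null, null_seed=seed)
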