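"""Network measures on binary graphs and parcellation-defined subgraphs.

Four whole-graph measures are computed: mean degree (overall connectivity),
global efficiency (integration: mean reciprocal shortest-path length),
Newman modularity against the fixed parcellation partition (segregation),
and average clustering coefficient (local cohesiveness).  Subgraph analysis
restricts the full graph to the nodes of one stream or one region; edges of
the subgraph are exactly the edges of the full graph joining retained nodes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse import csgraph

from .graph import BinaryGraph
from .parcellation import Parcellation

log = logging.getLogger(__name__)

GLOBAL_SCOPE = "global"


def mean_degree(g: BinaryGraph) -> float:
    """Average number of edges per node: 2k / n."""
    if g.n < 1:
        raise ValueError("mean_degree needs at least 1 node")
    return float(g.degrees().mean())


def global_efficiency(g: BinaryGraph, batch_size: int = 256) -> float:
    """Mean reciprocal shortest-path length over ordered distinct pairs.

    Distances are hop counts from per-source breadth-first search, run in
    source batches so that only a (batch × n) distance block is ever held in
    memory; unreachable pairs contribute zero.
    """
    n = g.n
    if n < 2:
        raise ValueError("global_efficiency needs at least 2 nodes")
    if g.k == 0:
        return 0.0
    total = 0.0
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        d = csgraph.dijkstra(g.adj, unweighted=True, directed=False, indices=idx)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0  # unreachable pairs and self-distances
        total += inv.sum()
    return total / (n * (n - 1))


def _labels_positional(g: BinaryGraph, p: Parcellation, level: str) -> np.ndarray:
    """Community label per graph node, in graph node order."""
    if level == "region":
        lab = dict(zip(p.node_ids, p.region_of_node))
    elif level == "stream":
        lab = dict(zip(p.node_ids, p.stream_of_node()))
    else:
        raise ValueError("level must be 'region' or 'stream'")
    try:
        return np.array([lab[v] for v in g.node_ids], dtype=object)
    except KeyError as exc:
        raise KeyError(f"node {exc.args[0]!r} missing from parcellation") from exc


def modularity(g: BinaryGraph, p: Parcellation, level: str = "region") -> float:
    """Newman modularity of the fixed parcellation partition.

    Q = (1/2k) * sum_ij (A_ij - d_i d_j / 2k) * delta(r_i, r_j), the excess
    of within-community edges over the degree-preserving random expectation.
    Undefined (raises) on an edgeless graph.
    """
    k = g.k
    if k == 0:
        raise ValueError("modularity is undefined for a graph with no edges")
    labels = _labels_positional(g, p, level)
    _, codes = np.unique(labels, return_inverse=True)
    n_comm = codes.max() + 1
    deg = g.degrees().astype(float)
    edges = g.edge_array()
    within = codes[edges[:, 0]] == codes[edges[:, 1]]
    m_within = np.bincount(codes[edges[within, 0]], minlength=n_comm).astype(float)
    deg_sum = np.bincount(codes, weights=deg, minlength=n_comm)
    two_k = 2.0 * k
    return float((m_within / k - (deg_sum / two_k) ** 2).sum())


def clustering_coefficients(g: BinaryGraph) -> np.ndarray:
    """Per-node clustering: fraction of neighbor pairs that are connected.

    Nodes of degree < 2 have no neighbor pair; their coefficient is defined
    as 0 here.
    """
    deg = g.degrees().astype(float)
    a = g.adj
    # ordered connected neighbor pairs of i = (A @ A) ∘ A row sums = diag(A^3)
    paths2 = (a @ a).multiply(a)
    closed = np.asarray(paths2.sum(axis=1)).ravel().astype(float)
    denom = deg * (deg - 1.0)
    c = np.zeros(g.n)
    ok = denom > 0
    c[ok] = closed[ok] / denom[ok]
    return c


def avg_clustering(g: BinaryGraph, exclude_low_degree: bool = False) -> float:
    """Mean clustering coefficient over nodes.

    By default degree-0/1 nodes enter the average with coefficient 0; with
    ``exclude_low_degree`` they are dropped from the mean instead (0 is
    returned if no node has degree >= 2).
    """
    if g.n < 1:
        raise ValueError("avg_clustering needs at least 1 node")
    c = clustering_coefficients(g)
    if exclude_low_degree:
        keep = g.degrees() >= 2
        if not keep.any():
            return 0.0
        return float(c[keep].mean())
    return float(c.mean())


def induced_subgraph(g: BinaryGraph, nodes) -> BinaryGraph:
    """Subgraph on node subset V' keeping exactly the edges within V'."""
    return g.subgraph(nodes)


def metric_battery(
    g: BinaryGraph,
    p: Parcellation,
    modularity_level: str = "region",
    clustering_excludes_low_degree: bool = False,
    scopes: tuple = ("global", "streams", "regions"),
) -> pd.DataFrame:
    """Long-format metric rows for one graph at every analysis scope.

    * global scope: mean degree, efficiency, modularity (parcellation
      partition at ``modularity_level``), clustering;
    * each stream subgraph: mean degree, efficiency, clustering, and
      modularity of the region partition restricted to the stream;
    * each region subgraph: efficiency only.

    Modularity rows are omitted when the (sub)graph has no edges, since the
    measure is undefined there; single-node scopes skip efficiency.
    ``scopes`` restricts which scope families are computed (simulation
    studies that only analyze some scopes can skip the rest).
    """
    rows: list[dict] = []

    def add(scope: str, metric: str, value: float):
        rows.append({"scope": scope, "metric": metric, "value": float(value)})

    def basic(sub: BinaryGraph, scope: str, with_clustering=True):
        add(scope, "mean_degree", mean_degree(sub))
        if sub.n >= 2:
            add(scope, "efficiency", global_efficiency(sub))
        if with_clustering:
            add(scope, "clustering",
                avg_clustering(sub, clustering_excludes_low_degree))

    if "global" in scopes:
        basic(g, GLOBAL_SCOPE)
        if g.k > 0:
            add(GLOBAL_SCOPE, "modularity", modularity(g, p, modularity_level))

    if "streams" in scopes:
        for stream in p.streams:
            nodes = p.nodes_in_stream(stream)
            if len(nodes) == 0:
                log.warning("stream %r has no nodes; rows omitted", stream)
                continue
            sub = induced_subgraph(g, nodes)
            scope = f"stream:{stream}"
            basic(sub, scope)
            if sub.k > 0:
                add(scope, "modularity", modularity(sub, p, "region"))

    if "regions" in scopes:
        for region in p.regions:
            nodes = p.nodes_in_region(region)
            if len(nodes) == 0:
                log.warning("region %r has no nodes; rows omitted", region)
                continue
            sub = induced_subgraph(g, nodes)
            if sub.n >= 2:
                add(f"region:{region}", "efficiency", global_efficiency(sub))

    return pd.DataFrame(rows, columns=["scope", "metric", "value"])
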