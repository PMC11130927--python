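"""From one timeseries recording to a thresholded functional-connectivity graph.

One recording is a nodes × timepoints matrix of BOLD-like signals.  Pairwise
product-moment (Pearson) correlations are tested with the parametric t
transform at T − 2 degrees of freedom, the upper-triangle p-values are
corrected for multiple comparisons by a false-discovery-rate step-up
procedure at level ``q_star``, and the surviving pairs become the edges of a
binary, undirected, simple graph.  Correlation magnitudes are discarded: the
analysis downstream is purely topological.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .graph import BinaryGraph

log = logging.getLogger(__name__)


@dataclass
class TimeseriesMatrix:
    """One subject/condition/clip recording: nodes × timepoints."""

    node_ids: np.ndarray  # shape (n,), str
    values: np.ndarray    # shape (n, T), float

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.node_ids):
            raise ValueError("values must be (n_nodes, timepoints)")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        if self.values.shape[1] < 8:
            raise ValueError("need at least 8 timepoints")
        if not np.isfinite(self.values).all():
            raise ValueError("timeseries contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def timepoints(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path, header_lines=()) -> None:
        df = pd.DataFrame(self.values, index=self.node_ids)
        df.index.name = "node_id"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "TimeseriesMatrix":
        df = pd.read_csv(path, sep="\t", index_col="node_id", comment="#")
        return cls(df.index.to_numpy(dtype=object), df.to_numpy(dtype=float))


@dataclass
class CorrelationResult:
    node_ids: np.ndarray
    r: np.ndarray             # symmetric, diagonal set to 0 (unused)
    p: np.ndarray             # symmetric two-sided p-values, diagonal 1
    dof: int
    constant_mask: np.ndarray  # nodes flagged for zero temporal variance

    @property
    def n(self) -> int:
        return len(self.node_ids)


def pearson_matrix(ts: TimeseriesMatrix) -> CorrelationResult:
    """All-pairs sample Pearson correlations with parametric p-values.

    ``p_ij`` comes from ``t = r * sqrt((T-2) / (1 - r^2))`` against a
    two-sided Student t distribution with ``T - 2`` degrees of freedom.
    A node with zero temporal variance has no defined correlation; such
    nodes are flagged and all their pairs get ``r = 0``, ``p = 1`` so they
    can never contribute edges.
    """
    X = ts.values
    n, T = X.shape
    dof = T - 2
    sd = X.std(axis=1)
    # a numerically constant series (std at rounding-error scale) has no
    # meaningful correlation either
    scale = np.maximum(1.0, np.abs(X).max(axis=1))
    constant = sd <= 1e-12 * scale
    if constant.any():
        log.warning("%d constant node timeseries flagged (pairs set to p=1)",
                    int(constant.sum()))
    Z = np.zeros_like(X)
    ok = ~constant
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    r = (Z @ Z.T) / T
    np.clip(r, -1.0, 1.0, out=r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 0.0)

    # p-values on the upper triangle only, mirrored afterwards; two-sided
    # survival of Student t via the direct special function (much cheaper
    # than the scipy.stats distribution machinery)
    iu, ju = np.triu_indices(n, k=1)
    r_u = r[iu, ju]
    with np.errstate(divide="ignore"):
        t_u = r_u * np.sqrt(dof / np.maximum(1.0 - r_u * r_u, np.finfo(float).tiny))
    p_u = 2.0 * special.stdtr(dof, -np.abs(t_u))
    np.clip(p_u, 0.0, 1.0, out=p_u)
    p_u[np.abs(r_u) >= 1.0] = 0.0  # the t statistic diverges, p -> 0
    p = np.ones((n, n))
    p[iu, ju] = p_u
    p[ju, iu] = p_u
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 1.0)
    return CorrelationResult(ts.node_ids.copy(), r, p, dof, constant)


_FDR_METHODS = {"bh": "fdr_bh", "by": "fdr_by"}


def fdr_threshold(
    c: CorrelationResult,
    q_star: float = 0.001,
    method: str = "bh",
    positive_only: bool = False,
) -> BinaryGraph:
    """Binarize a correlation matrix by FDR control over the n(n-1)/2 pairs.

    The step-up procedure (Benjamini–Hochberg by default, Benjamini–
    Yekutieli with ``method="by"``) is applied to the upper-triangle
    p-values at level ``q_star``; pair (i, j) becomes an edge iff its
    p-value survives.  With ``positive_only`` set, surviving pairs with a
    negative correlation are additionally dropped.
    """
    if not 0.0 < q_star < 1.0:
        raise ValueError("q_star must lie strictly inside (0, 1)")
    if method not in _FDR_METHODS:
        raise ValueError(f"unknown FDR method {method!r}; use 'bh' or 'by'")
    n = c.n
    if n == 0:
        raise ValueError("empty node set")
    iu, ju = np.triu_indices(n, k=1)
    pvals = c.p[iu, ju]
    if pvals.size == 0:
        return BinaryGraph.from_edges(c.node_ids, [])
    reject = multipletests(pvals, alpha=q_star, method=_FDR_METHODS[method])[0]
    if positive_only:
        reject &= c.r[iu, ju] > 0
    edges = np.column_stack([iu[reject], ju[reject]])
    return BinaryGraph.from_edges(c.node_ids, edges)


def connectivity_graph(
    ts: TimeseriesMatrix,
    q_star: float = 0.001,
    method: str = "bh",
    positive_only: bool = False,
) -> BinaryGraph:
    """Fused correlation → FDR-threshold path for one recording.

    Produces exactly the same graph as ``fdr_threshold(pearson_matrix(ts))``
    (asserted in the test suite) but avoids materializing all m p-values:
    only pairs with p ≤ q* can ever be rejected by the step-up rule, so
    p-values are evaluated just for those candidates and the step-up is run
    against the full-m slope.
    """
    if not 0.0 < q_star < 1.0:
        raise ValueError("q_star must lie strictly inside (0, 1)")
    if method not in _FDR_METHODS:
        raise ValueError(f"unknown FDR method {method!r}; use 'bh' or 'by'")
    X = ts.values
    n, T = X.shape
    dof = T - 2
    sd = X.std(axis=1)
    scale = np.maximum(1.0, np.abs(X).max(axis=1))
    constant = sd <= 1e-12 * scale
    Z = np.zeros_like(X)
    ok = ~constant
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    r = (Z @ Z.T) / T
    np.clip(r, -1.0, 1.0, out=r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 0.0)

    iu, ju = np.triu_indices(n, k=1)
    r_u = r[iu, ju]
    m = len(r_u)
    if m == 0:
        return BinaryGraph.from_edges(ts.node_ids, [])
    # candidate pairs: p <= q*, i.e. |t| >= t_cut, i.e. |r| >= r_cut
    t_cut = -special.stdtrit(dof, q_star / 2.0)
    r_cut = t_cut / np.sqrt(dof + t_cut * t_cut)
    cand = np.abs(r_u) >= r_cut
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return BinaryGraph.from_edges(ts.node_ids, [])
    r_c = r_u[idx]
    with np.errstate(divide="ignore"):
        t_c = np.abs(r_c) * np.sqrt(
            dof / np.maximum(1.0 - r_c * r_c, np.finfo(float).tiny))
    p_c = 2.0 * special.stdtr(dof, -t_c)
    np.clip(p_c, 0.0, 1.0, out=p_c)
    p_c[np.abs(r_c) >= 1.0] = 0.0
    # step-up over the full family of m tests (BY divides by the harmonic sum)
    q_eff = q_star if method == "bh" else q_star / np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p_c, kind="stable")
    ranks = np.arange(1, idx.size + 1)
    passing = p_c[order] <= ranks * q_eff / m
    k_star = int(np.max(np.nonzero(passing)[0]) + 1) if passing.any() else 0
    reject = np.zeros(idx.size, dtype=bool)
    reject[order[:k_star]] = True
    if positive_only:
        reject &= r_c > 0
    keep = idx[reject]
    return BinaryGraph.from_edges(
        ts.node_ids, np.column_stack([iu[keep], ju[keep]]))


def proportion_retained(g: BinaryGraph) -> float:
    """Fraction of possible node pairs kept as edges: k / (n(n-1)/2)."""
    if g.n < 2:
        raise ValueError("proportion_retained needs at least 2 nodes")
    return g.k / (g.n * (g.n - 1) / 2)
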