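"""Binary undirected graph container.

Graphs here are always simple, unweighted and undirected: the adjacency
matrix is symmetric 0/1 with an empty diagonal, and the edge count ``k`` is
half the adjacency sum.  Node identity (string ids) is preserved through
subgraph operations so that parcellation lookups remain valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass
class BinaryGraph:
    node_ids: np.ndarray      # shape (n,), str
    adj: sp.csr_matrix        # shape (n, n), int8, symmetric, zero diagonal
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.node_ids)
        if self.adj.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node ids")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dense(cls, node_ids, dense) -> "BinaryGraph":
        dense = np.asarray(dense)
        if not np.array_equal(dense, dense.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(dense) != 0):
            raise ValueError("adjacency must have an empty diagonal")
        if not np.isin(dense, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        return cls(np.asarray(node_ids, dtype=object), sp.csr_matrix(dense, dtype=np.int8))

    @classmethod
    def from_edges(cls, node_ids, edges) -> "BinaryGraph":
        """Build from an iterable of (i, j) positional index pairs."""
        node_ids = np.asarray(node_ids, dtype=object)
        n = len(node_ids)
        edges = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValueError("edge index out of range")
        if edges.size and np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        rows = np.concatenate([edges[:, 0], edges[:, 1]])
        cols = np.concatenate([edges[:, 1], edges[:, 0]])
        data = np.ones(len(rows), dtype=np.int8)
        adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n), dtype=np.int8)
        adj.data[:] = 1  # collapse duplicate edge entries
        return cls(node_ids, adj)

    # -- basic properties ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def k(self) -> int:
        return int(self.adj.sum()) // 2

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adj.sum(axis=1)).ravel().astype(np.int64)

    def index_of(self) -> dict:
        if self._index is None:
            object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.node_ids)})
        return self._index

    def edge_array(self) -> np.ndarray:
        """Upper-triangle edges as an (k, 2) array of positional indices."""
        coo = sp.triu(self.adj, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order]])

    def subgraph(self, nodes) -> "BinaryGraph":
        """Induced subgraph on the given node ids (order preserved)."""
        idx_map = self.index_of()
        try:
            idx = np.array([idx_map[v] for v in nodes], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown node id {exc.args[0]!r}") from exc
        sub = self.adj[idx][:, idx].tocsr()
        return BinaryGraph(np.asarray(nodes, dtype=object), sub)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for i, j in self.edge_array():
            g.add_edge(self.node_ids[i], self.node_ids[j])
        return g

    def is_same_graph(self, other: "BinaryGraph") -> bool:
        return (
            np.array_equal(self.node_ids, other.node_ids)
            and (self.adj != other.adj).nnz == 0
        )

    # -- edge-list serialization -------------------------------------------

    def write_edgelist(self, path, header_lines=()) -> None:
        """Whitespace-delimited edge list, one edge per line, i < j by node order.

        The header carries the node universe size and edge count so a graph
        with isolated nodes round-trips.
        """
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# n_nodes={self.n} n_edges={self.k}\n")
            for i, j in self.edge_array():
                fh.write(f"{self.node_ids[i]}\t{self.node_ids[j]}\n")

    @classmethod
    def read_edgelist(cls, path, node_ids) -> "BinaryGraph":
        """Read an edge list against a known node universe (e.g. a parcellation)."""
        node_ids = np.asarray(node_ids, dtype=object)
        idx = {v: i for i, v in enumerate(node_ids)}
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split()
                if a not in idx or b not in idx:
                    bad = a if a not in idx else b
                    raise KeyError(f"unknown node id {bad!r} in {path}")
                edges.append((idx[a], idx[b]))
        return cls.from_edges(node_ids, edges)
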