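"""Node-to-region-to-stream parcellation.

A parcellation is a total assignment of graph nodes to named cortical areas
(regions), each of which belongs to exactly one processing stream.  Region
membership provides the fixed community partition used by modularity and
defines the induced subgraphs analyzed at stream and region scope; no
community detection is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigError


@dataclass(frozen=True)
class Parcellation:
    node_ids: np.ndarray       # shape (n,), str
    region_of_node: np.ndarray  # shape (n,), str region label per node
    stream_of_region: dict     # region label -> stream label

    def __post_init__(self):
        if len(self.node_ids) != len(self.region_of_node):
            raise ValueError("node_ids and region_of_node length mismatch")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        missing = set(np.unique(self.region_of_node)) - set(self.stream_of_region)
        if missing:
            raise ValueError(f"regions without stream assignment: {sorted(missing)}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def regions(self) -> list[str]:
        """Region labels in first-appearance (node) order."""
        seen: dict[str, None] = {}
        for r in self.region_of_node:
            seen.setdefault(r, None)
        return list(seen)

    @property
    def streams(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(self.stream_of_region[r], None)
        return list(seen)

    def stream_of_node(self) -> np.ndarray:
        return np.array([self.stream_of_region[r] for r in self.region_of_node])

    def nodes_in_region(self, region: str) -> np.ndarray:
        return self.node_ids[self.region_of_node == region]

    def nodes_in_stream(self, stream: str) -> np.ndarray:
        return self.node_ids[self.stream_of_node() == stream]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "region": self.region_of_node,
                "stream": [self.stream_of_region[r] for r in self.region_of_node],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        required = {"node_id", "region", "stream"}
        if not required.issubset(df.columns):
            raise ValueError(f"parcellation table needs columns {sorted(required)}")
        stream_of_region: dict[str, str] = {}
        for region, stream in zip(df["region"], df["stream"]):
            prev = stream_of_region.setdefault(region, stream)
            if prev != stream:
                raise ValueError(f"region {region!r} mapped to multiple streams")
        return cls(
            node_ids=df["node_id"].to_numpy(dtype=object),
            region_of_node=df["region"].to_numpy(dtype=object),
            stream_of_region=stream_of_region,
        )

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#", dtype=str))


def generate_parcellation(config: CohortConfig) -> Parcellation:
    """Deterministically lay out nodes region-by-region in config order.

    Node ids are ``n0000 ... n{N-1}``; the first ``count`` nodes belong to the
    first region, and so on.  Raises :class:`ConfigError` when region names
    repeat or counts do not sum to ``n_nodes`` (delegated to config
    validation).
    """
    config.validate()
    width = max(4, len(str(config.n_nodes - 1)))
    node_ids = np.array([f"n{i:0{width}d}" for i in range(config.n_nodes)], dtype=object)
    region_of_node = np.empty(config.n_nodes, dtype=object)
    stream_of_region: dict[str, str] = {}
    pos = 0
    for name, stream, count in config.regions:
        region_of_node[pos : pos + count] = name
        stream_of_region[name] = stream
        pos += count
    if pos != config.n_nodes:  # defensive; config.validate() already checks
        raise ConfigError("region node counts do not cover n_nodes")
    return Parcellation(node_ids, region_of_node, stream_of_region)
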