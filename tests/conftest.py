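import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from fcnet import BinaryGraph, CohortConfig, Parcellation


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_config():
    """Four one-region streams, 40 nodes: quick but structurally complete."""
    return CohortConfig(
        n_patients=4,
        n_controls=6,
        n_nodes=40,
        timepoints=24,
        regions=(
            ("V1_L", "early", 10),
            ("VO1_L", "ventral", 10),
            ("V3a_L", "dorsal", 10),
            ("IPS1_L", "fronto-parietal", 10),
        ),
        base_within_region_edge_prob=0.8,
        base_between_region_edge_prob=0.05,
        delta_density_patient=0.1,
        delta_between_patient=0.02,
        delta_condition_3d=0.01,
        spared_streams=("early",),
        signal_to_noise=5.0,
        seed=11,
    ).validate()


def graph_from_dense(adj, ids=None):
    adj = np.asarray(adj)
    if ids is None:
        ids = [f"v{i}" for i in range(adj.shape[0])]
    return BinaryGraph.from_dense(ids, adj)


def parcellation_of(labels, streams=None):
    """Parcellation over nodes v0..v{n-1} from a label list."""
    labels = list(labels)
    ids = np.array([f"v{i}" for i in range(len(labels))], dtype=object)
    uniq = list(dict.fromkeys(labels))
    if streams is None:
        streams = {r: "early" for r in uniq}
    return Parcellation(ids, np.array(labels, dtype=object), streams)
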