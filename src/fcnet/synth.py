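"""Planted-effect cohort simulation.

The generator emulates the statistical structure the downstream analysis
assumes, not fMRI physics.  Each recording starts from a planted binary
graph drawn from a stochastic block model whose communities are the
parcellation regions; group and condition membership shift the block edge
probabilities (see :class:`~fcnet.config.CohortConfig`).  The recording's
timeseries are then drawn i.i.d. across timepoints from a zero-mean
multivariate normal with covariance

    Sigma = snr * A + c * I,

where ``A`` is the planted adjacency and ``c = snr * max(0, -lambda_min(A))
+ margin`` is the smallest diagonal loading that makes the matrix positive
definite, plus a fixed margin.  Under this model the population correlation
of an adjacent pair is ``snr / c`` and of a non-adjacent pair exactly zero,
so sample Pearson correlation concentrates edges on the planted graph.

Randomness is drawn from per-recording substreams keyed by (subject index,
condition index, clip index) off a single master seed, so a cohort is
bit-reproducible and enlarging it never perturbs earlier subjects' data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .config import CohortConfig
from .fc import TimeseriesMatrix
from .graph import BinaryGraph
from .parcellation import Parcellation, generate_parcellation

PD_MARGIN = 0.5  # fixed diagonal margin added beyond positive definiteness

GROUP_PATIENT = "mTBI"
GROUP_CONTROL = "control"
_GROUP_ALIASES = {"patient": GROUP_PATIENT, "mtbi": GROUP_PATIENT,
                  GROUP_PATIENT: GROUP_PATIENT, GROUP_CONTROL: GROUP_CONTROL}


def _canon_group(group: str) -> str:
    try:
        return _GROUP_ALIASES[group if group in _GROUP_ALIASES else group.lower()]
    except KeyError:
        raise ValueError(f"group must be patient/mTBI or control, got {group!r}")


@lru_cache(maxsize=64)
def _parcellation_cached(config: CohortConfig) -> Parcellation:
    return generate_parcellation(config)


@lru_cache(maxsize=64)
def _probs_cached(config: CohortConfig, group: str, condition: str) -> np.ndarray:
    config.validate()
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}; expected {config.conditions}")
    parc = _parcellation_cached(config)
    region = parc.region_of_node
    stream = parc.stream_of_node()
    within = region[:, None] == region[None, :]
    prob = np.where(within, config.base_within_region_edge_prob,
                    config.base_between_region_edge_prob)
    if group == GROUP_PATIENT:
        spared = np.isin(stream, config.spared_streams)
        affected = ~(spared[:, None] | spared[None, :])
        prob = prob + np.where(affected & within, config.delta_density_patient, 0.0)
        prob = prob + np.where(affected & ~within, config.delta_between_patient, 0.0)
    if condition == "3D":
        prob = prob + config.delta_condition_3d
    np.fill_diagonal(prob, 0.0)
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError("effective edge probability outside [0, 1]")
    prob.flags.writeable = False
    return prob


def expected_edge_probabilities(
    config: CohortConfig, group: str, condition: str
) -> np.ndarray:
    """Dense matrix of pair-wise planted edge probabilities (diagonal 0).

    Encodes the full effect structure: within/between-region base rates, the
    patient density and mixing increments (suppressed on pairs touching a
    spared stream), and the global 3D condition increment.
    """
    return _probs_cached(config, _canon_group(group), condition).copy()


def plant_subject_graph(
    config: CohortConfig, group: str, condition: str, rng: np.random.Generator
) -> BinaryGraph:
    """Draw one subject-recording graph from the block model.

    Each unordered node pair is an independent Bernoulli draw at the
    pair's effective probability; the result is simple and undirected.
    """
    prob = _probs_cached(config, _canon_group(group), condition)
    n = config.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(len(iu)) < prob[iu, ju]
    parc = _parcellation_cached(config)
    return BinaryGraph.from_edges(parc.node_ids, np.column_stack([iu[hit], ju[hit]]))


def covariance_from_graph(
    adj_dense: np.ndarray,
    signal_to_noise: float,
    lambda_floor: float | None = None,
) -> np.ndarray:
    """Sigma = snr * A + c * I with positive-definite diagonal loading + margin.

    With ``lambda_floor=None`` the loading is the minimal one for this graph,
    ``c = snr * max(0, -lambda_min(A)) + margin``.  A cohort generator should
    instead pass a common ``lambda_floor`` (an upper bound on ``-lambda_min``
    across the cohort design, see :func:`cohort_lambda_floor`): a shared
    loading keeps the edge correlation ``snr / c`` identical across groups
    and conditions, whereas per-recording minimal loading would couple
    correlation strength to planted density and so distort group contrasts.
    """
    adj_dense = np.asarray(adj_dense, dtype=float)
    if not np.array_equal(adj_dense, adj_dense.T):
        raise ValueError("adjacency must be symmetric")
    lam_min = float(np.linalg.eigvalsh(adj_dense)[0]) if adj_dense.shape[0] else 0.0
    needed = max(0.0, -lam_min)
    load = needed if lambda_floor is None else max(lambda_floor, needed)
    c = signal_to_noise * load + PD_MARGIN
    sigma = signal_to_noise * adj_dense + c * np.eye(adj_dense.shape[0])
    return sigma


def graph_to_timeseries(
    g: BinaryGraph,
    timepoints: int,
    signal_to_noise: float,
    rng: np.random.Generator,
    lambda_floor: float | None = None,
) -> TimeseriesMatrix:
    """Sample a recording whose correlation structure mirrors the graph.

    Timepoints are i.i.d. draws from N(0, Sigma) with Sigma as in
    :func:`covariance_from_graph`; adjacent node pairs share covariance
    ``snr`` while non-adjacent pairs are uncorrelated.
    """
    if timepoints < 8:
        raise ValueError("need at least 8 timepoints")
    adj = g.adj.toarray()
    if lambda_floor is not None:
        # The floor almost always dominates the per-graph requirement; try it
        # directly and only fall back to the exact eigenvalue when the
        # resulting matrix is not positive definite.
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        c = signal_to_noise * lambda_floor + PD_MARGIN
        sigma = signal_to_noise * adj + c * np.eye(g.n)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            sigma = covariance_from_graph(adj, signal_to_noise, lambda_floor)
            chol = np.linalg.cholesky(sigma)
    else:
        sigma = covariance_from_graph(adj, signal_to_noise, lambda_floor)
        chol = np.linalg.cholesky(sigma)
    values = chol @ rng.standard_normal((g.n, timepoints))
    return TimeseriesMatrix(g.node_ids.copy(), values)


_FLOOR_SEED = 202_401  # fixed internal seed: the floor is a design constant
_FLOOR_DRAWS = 8
_FLOOR_QUANTILE = 0.9
_FLOOR_PAD = 0.1


@lru_cache(maxsize=32)
def _lambda_floor_cached(design: CohortConfig) -> float:
    rng = np.random.default_rng(np.random.SeedSequence(_FLOOR_SEED))
    needs = []
    for group in (GROUP_CONTROL, GROUP_PATIENT):
        for condition in design.conditions:
            for _ in range(_FLOOR_DRAWS):
                g = plant_subject_graph(design, group, condition, rng)
                lam = float(np.linalg.eigvalsh(g.adj.toarray().astype(float))[0])
                needs.append(max(0.0, -lam))
    return float(np.quantile(needs, _FLOOR_QUANTILE) + _FLOOR_PAD)


def cohort_lambda_floor(config: CohortConfig) -> float:
    """Common diagonal-loading floor for every recording of a cohort design.

    Estimated as a high quantile of ``-lambda_min`` over a fixed-seed set of
    draws from each group × condition cell, plus a pad; the occasional
    recording whose own requirement exceeds the floor falls back to its
    minimal loading.  Depends only on the design (the cohort seed is
    ignored), so replicate cohorts of one design share the same signal
    scaling.
    """
    return _lambda_floor_cached(config.with_(seed=0))


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class Recording:
    subject_id: str
    group: str
    condition: str
    clip: int
    planted_graph: BinaryGraph
    timeseries: TimeseriesMatrix
    seed_key: tuple[int, int, int]


@dataclass
class SyntheticTruth:
    """Provenance of a generated cohort.

    The config (including its master seed) regenerates the cohort
    bit-identically; per-recording entries record the substream key actually
    consumed plus the planted graph's edge count for spot checks.
    """

    config: CohortConfig
    records: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {"config": self.config.to_dict(), "records": self.records}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(CohortConfig.from_dict(payload["config"]), payload["records"])


def subject_table(config: CohortConfig) -> pd.DataFrame:
    """Subject ids and group labels: patients first, then controls."""
    width = max(3, len(str(config.n_patients + config.n_controls)))
    rows = []
    for s in range(config.n_patients + config.n_controls):
        group = GROUP_PATIENT if s < config.n_patients else GROUP_CONTROL
        rows.append({"subject_id": f"sub{s:0{width}d}", "group": group})
    return pd.DataFrame(rows)


def recording_rng(config: CohortConfig, subject_idx: int, cond_idx: int,
                  clip_idx: int) -> np.random.Generator:
    """Counter-keyed substream off the master seed for one recording."""
    ss = np.random.SeedSequence(config.seed,
                                spawn_key=(subject_idx, cond_idx, clip_idx))
    return np.random.default_rng(ss)


def iter_recordings(config: CohortConfig) -> Iterator[Recording]:
    """Generate the full cohort recording-by-recording, in manifest order."""
    config.validate()
    subjects = subject_table(config)
    floor = cohort_lambda_floor(config)
    for s_idx, row in subjects.iterrows():
        for c_idx, condition in enumerate(config.conditions):
            for clip in range(1, config.clips_per_condition + 1):
                rng = recording_rng(config, s_idx, c_idx, clip - 1)
                g = plant_subject_graph(config, row["group"], condition, rng)
                ts = graph_to_timeseries(
                    g, config.timepoints, config.signal_to_noise, rng,
                    lambda_floor=floor,
                )
                yield Recording(row["subject_id"], row["group"], condition,
                                clip, g, ts, (s_idx, c_idx, clip - 1))


def generate_cohort(
    config: CohortConfig, outdir, header_lines=()
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Write a cohort to disk: parcellation, timeseries TSVs, manifest, truth.

    Returns the manifest frame (columns subject_id, group, condition, clip,
    path) and the :class:`SyntheticTruth` record.  Layout::

        outdir/
          parcellation.tsv
          manifest.tsv
          truth.json
          ts/<subject>_<condition>_clip<j>.tsv
    """
    outdir = Path(outdir)
    (outdir / "ts").mkdir(parents=True, exist_ok=True)
    parc = generate_parcellation(config)
    parc.to_tsv(outdir / "parcellation.tsv")
    truth = SyntheticTruth(config)
    manifest_rows = []
    for rec in iter_recordings(config):
        rel = f"ts/{rec.subject_id}_{rec.condition}_clip{rec.clip}.tsv"
        rec.timeseries.to_tsv(outdir / rel, header_lines=header_lines)
        manifest_rows.append(
            {"subject_id": rec.subject_id, "group": rec.group,
             "condition": rec.condition, "clip": rec.clip, "path": rel}
        )
        truth.records.append(
            {"subject_id": rec.subject_id, "group": rec.group,
             "condition": rec.condition, "clip": rec.clip,
             "seed_key": list(rec.seed_key),
             "planted_edges": rec.planted_graph.k}
        )
    manifest = pd.DataFrame(
        manifest_rows, columns=["subject_id", "group", "condition", "clip", "path"]
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    return manifest, truth


def parcellation_for(config: CohortConfig) -> Parcellation:
    return generate_parcellation(config)
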