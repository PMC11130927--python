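"""In-memory end-to-end analysis: simulate → correlate → threshold → metrics → stats.

The disk-based CLI stages wrap the same building blocks; this module exists
so that simulation studies (many cohort replicates) can run without file
round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import fc, metrics, stats, synth
from .config import CohortConfig, PipelineConfig
from .parcellation import Parcellation


@dataclass
class CohortAnalysis:
    metric_table: pd.DataFrame     # long format incl. subject/group/condition/clip
    results: pd.DataFrame          # one row per metric × scope
    retained: pd.DataFrame         # proportion of pairs kept per recording


def analyze_recording(
    ts: fc.TimeseriesMatrix,
    parc: Parcellation,
    config: PipelineConfig,
    scopes: tuple = ("global", "streams", "regions"),
) -> tuple[pd.DataFrame, float]:
    """Metric rows and retained-edge proportion for one recording."""
    g = fc.connectivity_graph(ts, config.q_star, config.fdr_method,
                              config.positive_only)
    battery = metrics.metric_battery(
        g, parc, config.modularity_level, config.clustering_excludes_low_degree,
        scopes=scopes,
    )
    return battery, fc.proportion_retained(g)


def cohort_metric_table(
    config: PipelineConfig,
    scopes: tuple = ("global", "streams", "regions"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort and compute the full long-format metric table."""
    cohort = config.cohort
    parc = synth.parcellation_for(cohort)
    frames = []
    retained_rows = []
    for rec in synth.iter_recordings(cohort):
        battery, retained = analyze_recording(rec.timeseries, parc, config, scopes)
        battery = battery.copy()
        battery.insert(0, "clip", rec.clip)
        battery.insert(0, "condition", rec.condition)
        battery.insert(0, "group", rec.group)
        battery.insert(0, "subject_id", rec.subject_id)
        frames.append(battery)
        retained_rows.append(
            {"subject_id": rec.subject_id, "group": rec.group,
             "condition": rec.condition, "clip": rec.clip,
             "proportion_retained": retained}
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(retained_rows)


def analyze_cohort(
    config: PipelineConfig,
    scopes: tuple = ("global", "streams", "regions"),
) -> CohortAnalysis:
    """Full pipeline on one simulated cohort."""
    config.validate()
    table, retained = cohort_metric_table(config, scopes)
    results = stats.run_group_models(table, config.clip_handling)
    return CohortAnalysis(table, results, retained)


def default_config(**cohort_overrides) -> PipelineConfig:
    """Pipeline defaults with optional cohort field overrides."""
    cohort = CohortConfig(**cohort_overrides).validate()
    return PipelineConfig(cohort=cohort).validate()
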