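"""Cohort and pipeline configuration objects.

The cohort configuration fixes the study design the simulator emulates: an
unbalanced two-group cohort (17 mTBI patients vs. 54 controls), a two-level
within-subject stimulus factor (2D vs. 3D movie viewing) with two clips per
condition, ~120 retained volumes per recording, and a visual-cortex style
parcellation whose areas group into four processing streams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

STREAMS = ("early", "dorsal", "ventral", "fronto-parietal")

# Desk-scale parcellation: retinotopic-atlas style visual areas per
# hemisphere (L/R), grouped into four processing streams, 8 nodes per
# region — 50 regions, 400 nodes.  The large early areas (V1–V3) are
# subdivided into foveal/peripheral eccentricity bands, reflecting their
# greater cortical extent.  Region order is node order.
_EARLY_AREAS = ("V1v", "V1d", "V2v", "V2d", "V3v", "V3d")
_HIGHER_AREAS: tuple[tuple[str, str], ...] = (
    ("hV4", "ventral"), ("VO1", "ventral"), ("VO2", "ventral"),
    ("PHC1", "ventral"), ("PHC2", "ventral"),
    ("V3a", "dorsal"), ("hMT", "dorsal"), ("MST", "dorsal"),
    ("IPS0", "dorsal"),
    ("IPS1", "fronto-parietal"), ("IPS2", "fronto-parietal"),
    ("IPS3", "fronto-parietal"), ("SPL1", "fronto-parietal"),
)

DEFAULT_REGIONS: tuple[tuple[str, str, int], ...] = tuple(
    (f"{area}_{hemi}_{band}", "early", 8)
    for hemi in ("L", "R")
    for area in _EARLY_AREAS
    for band in ("fov", "per")
) + tuple(
    (f"{area}_{hemi}", stream, 8)
    for hemi in ("L", "R")
    for area, stream in _HIGHER_AREAS
)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Design and generative parameters of one synthetic cohort.

    Edge probabilities define a stochastic block model over the parcellation:
    ``base_within_region_edge_prob`` for node pairs sharing a region,
    ``base_between_region_edge_prob`` otherwise.  Group and condition effects
    are planted as probability increments:

    * ``delta_density_patient`` — added to *within-region* pair probabilities
      for patients (raises connection density, hence degree and clustering);
    * ``delta_between_patient`` — added to *between-region* pair probabilities
      for patients (raises cross-community mixing, hence efficiency, and
      lowers modularity);
    * ``delta_condition_3d`` — added to every pair probability under the 3D
      condition (a global stimulus main effect, no group interaction).

    Patient deltas are suppressed on any pair with an endpoint in a stream
    listed in ``spared_streams``; by default the early visual stream is
    spared, so early-stream subgraphs are distribution-identical across
    groups while higher-order streams carry the planted effects.
    """

    n_patients: int = 17
    n_controls: int = 54
    n_nodes: int = 400
    timepoints: int = 120
    regions: tuple[tuple[str, str, int], ...] = field(default=DEFAULT_REGIONS)
    conditions: tuple[str, ...] = ("2D", "3D")
    clips_per_condition: int = 2
    base_within_region_edge_prob: float = 0.93
    base_between_region_edge_prob: float = 0.0001
    delta_density_patient: float = 0.065
    delta_between_patient: float = 0.0002
    delta_condition_3d: float = 0.0001
    spared_streams: tuple[str, ...] = ("early",)
    signal_to_noise: float = 10.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(tuple(r) for r in self.regions))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "spared_streams", tuple(self.spared_streams))

    def validate(self) -> "CohortConfig":
        if self.n_patients < 0 or self.n_controls < 0:
            raise ConfigError("group sizes must be nonnegative")
        if self.timepoints < 8:
            raise ConfigError("timepoints must be >= 8")
        if self.clips_per_condition < 1:
            raise ConfigError("clips_per_condition must be >= 1")
        if self.signal_to_noise <= 0:
            raise ConfigError("signal_to_noise must be positive")
        if not self.regions:
            raise ConfigError("region list must be nonempty")
        names = [r[0] for r in self.regions]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate region names")
        for name, stream, count in self.regions:
            if stream not in STREAMS:
                raise ConfigError(
                    f"region {name!r}: unknown stream {stream!r}; must be one of {STREAMS}"
                )
            if count < 1:
                raise ConfigError(f"region {name!r}: node count must be >= 1")
        total = sum(r[2] for r in self.regions)
        if total != self.n_nodes:
            raise ConfigError(
                f"region node counts sum to {total}, expected n_nodes={self.n_nodes}"
            )
        for s in self.spared_streams:
            if s not in STREAMS:
                raise ConfigError(f"unknown spared stream {s!r}")
        # Every effective edge probability must stay inside [0, 1].
        base = {
            "within": self.base_within_region_edge_prob,
            "between": self.base_between_region_edge_prob,
        }
        deltas = {
            "within": self.delta_density_patient,
            "between": self.delta_between_patient,
        }
        for kind in ("within", "between"):
            for group_delta in (0.0, deltas[kind]):
                for cond_delta in (0.0, self.delta_condition_3d):
                    p = base[kind] + group_delta + cond_delta
                    if not 0.0 <= p <= 1.0:
                        raise ConfigError(
                            f"effective {kind}-region edge probability {p:.4f} "
                            "outside [0, 1]"
                        )
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = [list(r) for r in self.regions]
        d["conditions"] = list(self.conditions)
        d["spared_streams"] = list(self.spared_streams)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown cohort config keys: {sorted(extra)}")
        return cls(**d).validate()

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs).validate()


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings: cohort design plus analysis switches."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    q_star: float = 0.001
    fdr_method: str = "bh"  # "bh" | "by"
    positive_only: bool = False
    clustering_excludes_low_degree: bool = False
    clip_handling: str = "average"  # "average" | "replicate"
    modularity_level: str = "region"  # "region" | "stream"
    outdir: str = "fcnet_out"

    def validate(self) -> "PipelineConfig":
        if not 0.0 < self.q_star < 1.0:
            raise ConfigError("q_star must lie strictly inside (0, 1)")
        if self.fdr_method not in ("bh", "by"):
            raise ConfigError("fdr_method must be 'bh' or 'by'")
        if self.clip_handling not in ("average", "replicate"):
            raise ConfigError("clip_handling must be 'average' or 'replicate'")
        if self.modularity_level not in ("region", "stream"):
            raise ConfigError("modularity_level must be 'region' or 'stream'")
        self.cohort.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        known = {f for f in cls.__dataclass_fields__} - {"cohort"}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown pipeline config keys: {sorted(extra)}")
        return cls(cohort=CohortConfig.from_dict(cohort), **d).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Short stable digest of the scientific configuration.

        The output directory is excluded: relocating a run must not
        invalidate its artifacts.
        """
        d = self.to_dict()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
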