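"""Pipeline configuration: every threshold of the analysis in one place.

Loaded from YAML, validated on load, and serialized into the provenance
section of every report the pipeline writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # signature phenotypes
    cloud_distance_bp: int = 1000
    n_attribution_restarts: int = 31
    exposure_threshold: float = 0.10
    pseudocount: float = 1.0
    # expression modules
    rho_min: float = 0.3
    p_adj_max: float = 0.005
    consensus_runs: int = 100
    k_range: tuple[int, int] = (5, 50)
    final_k: int = 7
    enrichment_p_max: float = 0.05
    # alteration matrix
    frequency_min: float = 0.01
    edge_score_min: float = 900.0
    # module search
    density_min: float = 0.5
    k_max: int = 7
    exclusivity_weight: float = 1.0
    min_increase: float = 0.05
    n_permutations: int = 100
    q_max: float = 0.1
    solver_time_limit: float = 600.0
    # randomness
    seed: int = 0
    # input paths (optional; stages that lack inputs are skipped)
    mutations: str | None = None
    expression: str | None = None
    network: str | None = None
    signature_catalog: str | None = None
    biallelic: str | None = None
    gene_sets: str | None = None
    exposures: str | None = None

    def __post_init__(self) -> None:
        checks = {
            "exposure_threshold": (0.0, 1.0),
            "rho_min": (0.0, 1.0),
            "p_adj_max": (0.0, 1.0),
            "frequency_min": (0.0, 1.0),
            "density_min": (0.0, 1.0),
            "min_increase": (0.0, 10.0),
            "q_max": (0.0, 1.0),
            "enrichment_p_max": (0.0, 1.0),
        }
        for name, (lo, hi) in checks.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("cloud_distance_bp", "n_attribution_restarts",
                     "consensus_runs", "final_k", "k_max", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.k_range = tuple(self.k_range)
        if len(self.k_range) != 2 or self.k_range[0] > self.k_range[1]:
            raise ValueError("k_range must be (lo, hi) with lo <= hi")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d
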