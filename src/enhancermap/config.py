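"""Pipeline configuration: every numeric threshold of the method in one record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Dict, Optional

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration value or key is invalid."""


@dataclass
class PipelineConfig:
    """Thresholds and sizes used across the enhancer-prediction pipeline.

    Defaults follow the published procedure: reciprocal 70% replicate peak
    overlap, the 20% methylation ceiling for low/unmethylated regions, 300-bp
    flanks with a 0.5 RPM floor and twofold ratio for H3K9ac asymmetry,
    the 635-bp TE baseline length filter, and 1000-draw permutation nulls.
    """

    replicate_overlap_frac: float = 0.70
    methylation_threshold: float = 0.20
    methylation_window_bp: int = 100
    methylation_min_sites: int = 4
    methylation_max_gap_bp: int = 300
    te_containment_frac: float = 0.80
    te_baseline_min_len_bp: int = 635
    orientation_flank_bp: int = 300
    asym_min_rpm: float = 0.5
    asym_fold: float = 2.0
    kmeans_k: int = 4
    heatmap_flank_bp: int = 1000
    body_bins: int = 50
    flank_bin_bp: int = 20
    n_permutations: int = 1000
    promoter_upstream_bp: int = 1000
    promoter_downstream_bp: int = 200
    flank_upstream_bp: int = 4000
    flank_downstream_bp: int = 5000
    expressed_min_rpkm: float = 1.0
    expression_bins: int = 6
    mappability_min_uniqueness: float = 0.90
    motif: str = "GGCCCA"
    random_seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "replicate_overlap_frac": self.replicate_overlap_frac,
            "methylation_threshold": self.methylation_threshold,
            "te_containment_frac": self.te_containment_frac,
            "mappability_min_uniqueness": self.mappability_min_uniqueness,
        }
        for name, val in fracs.items():
            if not (0 < val <= 1):
                raise ConfigError(f"{name} must be in (0, 1], got {val}")
        lengths = {
            "methylation_window_bp": self.methylation_window_bp,
            "te_baseline_min_len_bp": self.te_baseline_min_len_bp,
            "orientation_flank_bp": self.orientation_flank_bp,
            "heatmap_flank_bp": self.heatmap_flank_bp,
            "promoter_upstream_bp": self.promoter_upstream_bp,
            "promoter_downstream_bp": self.promoter_downstream_bp,
            "flank_upstream_bp": self.flank_upstream_bp,
            "flank_downstream_bp": self.flank_downstream_bp,
            "body_bins": self.body_bins,
            "flank_bin_bp": self.flank_bin_bp,
            "methylation_min_sites": self.methylation_min_sites,
            "methylation_max_gap_bp": self.methylation_max_gap_bp,
        }
        for name, val in lengths.items():
            if val <= 0:
                raise ConfigError(f"{name} must be > 0, got {val}")
        if self.n_permutations < 1:
            raise ConfigError(f"n_permutations must be >= 1, got {self.n_permutations}")
        if self.asym_fold < 1:
            raise ConfigError(f"asym_fold must be >= 1, got {self.asym_fold}")
        if self.asym_min_rpm < 0:
            raise ConfigError(f"asym_min_rpm must be >= 0, got {self.asym_min_rpm}")
        if self.kmeans_k < 1:
            raise ConfigError(f"kmeans_k must be >= 1, got {self.kmeans_k}")

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "PipelineConfig":
        unknown = set(d) - cls.field_names()
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)
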