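"""Run configuration for the full pipeline.

Defaults mirror the standard practice for this analysis: a scale-free fit
target of 0.8 for soft-threshold selection, eigengene merge cut height 0.2
(i.e. modules with eigengene correlation above 0.8 merge), DEG thresholds
|logFC| >= 0.5 at BH FDR 0.05, GO-style enrichment at adjusted p < 0.05
with overlap count strictly greater than 6, KEGG-style at adjusted p < 0.01,
STRING-scale interaction score cut 900 (0.9 combined confidence), and the
top 5 hub genes reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    beta_candidates: list[int] = field(default_factory=lambda: list(range(1, 13)))
    scale_free_target: float = 0.8
    min_module_size: int = 30
    merge_cut_height: float = 0.2
    cut_method: str = "adaptive"
    cut_quantile: float = 0.99
    deg_lfc_threshold: float = 0.5
    deg_fdr: float = 0.05
    enrich_go_fdr: float = 0.05
    enrich_kegg_fdr: float = 0.01
    enrich_min_count: int = 6
    ppi_min_score: float = 900.0
    top_k_hubs: int = 5
    network_sign: str = "unsigned"
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_candidates = [int(b) for b in self.beta_candidates]
        if not self.beta_candidates:
            raise ValueError("beta_candidates must be non-empty")
        if any(b < 1 for b in self.beta_candidates):
            raise ValueError("beta candidates must be positive integers")
        if self.beta_candidates != sorted(self.beta_candidates):
            raise ValueError("beta_candidates must be sorted ascending")
        if not 0 < self.scale_free_target <= 1:
            raise ValueError("scale_free_target must lie in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be a positive integer")
        if not 0 <= self.merge_cut_height <= 1:
            raise ValueError("merge_cut_height must lie in [0, 1]")
        if not 0 < self.cut_quantile < 1:
            raise ValueError("cut_quantile must lie in (0, 1)")
        if self.cut_method not in ("adaptive", "quantile"):
            raise ValueError("cut_method must be 'adaptive' or 'quantile'")
        if self.deg_lfc_threshold < 0:
            raise ValueError("deg_lfc_threshold must be non-negative")
        for name in ("deg_fdr", "enrich_go_fdr", "enrich_kegg_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.enrich_min_count < 0:
            raise ValueError("enrich_min_count must be non-negative")
        if self.top_k_hubs < 1:
            raise ValueError("top_k_hubs must be a positive integer")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValueError("network_sign must be 'unsigned' or 'signed'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat-key YAML config; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
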