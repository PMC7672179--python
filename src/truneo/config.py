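"""Run configuration: every numeric threshold of the pipeline in one place.

Defaults reproduce the published method; an empty config file therefore runs
the pipeline exactly as described.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # SNV filter
    snv_min_depth: int = 10
    snv_min_vaf_tumor: float = 0.05
    snv_max_vaf_normal: float = 0.02
    snv_min_adjacent_distance: int = 10  # strictly greater passes
    snv_min_mq_median: float = 30.0
    snv_mq_p_cutoff: float = 0.2
    snv_min_bq_median: float = 20.0
    snv_bq_p_cutoff: float = 0.05
    snv_dend_p_cutoff: float = 0.1
    # InDel filter
    indel_min_depth: int = 10
    indel_min_vaf_tumor: float = 0.10  # strictly greater passes
    indel_max_vaf_normal: float = 0.02
    # rank-sum implementation switch
    ranksum_exact_max_n: int = 25
    # HLA LOH
    loh_alpha: float = 0.0002
    loh_pseudocount: float | None = None  # None = drop zero-count sites
    # candidate filters
    min_rna_mut_reads: int = 1
    affinity_filter_nM: float = 500.0  # > 500 nM removed; exactly 500 kept
    # scoring
    combine_w_mhc: float = 0.8
    combine_w_cleavage: float = 0.15
    combine_w_tap: float = 0.05
    class_high_affinity_nM: float = 150.0
    type_weights: dict[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 0.6, 3: 0.5, 4: 0.25, 5: 0.15, 6: 0.125}
    )
    dl_tpm_cutoff: float = 15.0
    dl_affinity_cutoff_nM: float = 100.0
    dl_rank_cutoff: int = 30
    dl_identified_cutoff: float = 0.5
    expression_quartile_population: str = "positive"  # positive | all
    # high-confidence filter
    hc_min_vaf: float = 0.1
    hc_max_affinity_nM: float = 100.0
    hc_min_tpm: float = 15.0
    seed: int = 0

    def __post_init__(self):
        wsum = self.combine_w_mhc + self.combine_w_cleavage + self.combine_w_tap
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"CombineScore weights must sum to 1, got {wsum}")
        for name in (
            "snv_min_depth",
            "snv_min_vaf_tumor",
            "snv_max_vaf_normal",
            "indel_min_depth",
            "indel_min_vaf_tumor",
            "loh_alpha",
            "affinity_filter_nM",
            "hc_min_vaf",
            "hc_max_affinity_nM",
            "hc_min_tpm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load YAML or JSON; unknown keys rejected, missing keys defaulted."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping: {path}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "type_weights" in data:
            data["type_weights"] = {int(k): float(v) for k, v in data["type_weights"].items()}
        return cls(**data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
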