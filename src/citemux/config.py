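"""Pipeline configuration.

All numeric settings of the analysis live here so every stage reads the same
values: QC thresholds, normalization scale factors, graph/clustering
parameters, differential-expression filters and the per-stage random seeds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class Seeds:
    """Per-stage random seeds so stages can be re-run independently."""

    mixture: int = 0
    clustering: int = 0
    trajectory: int = 0

    @classmethod
    def from_base(cls, base: int) -> "Seeds":
        # distinct but reproducible streams per stage, kept below 2**31
        return cls(
            mixture=(base * 3 + 11) % (2**31),
            clustering=(base * 3 + 12) % (2**31),
            trajectory=(base * 3 + 13) % (2**31),
        )


@dataclass
class PipelineConfig:
    """Numeric settings for every pipeline stage.

    Defaults follow common droplet single-cell practice: cells with fewer
    than 400 detected genes are discarded, the top 500 jointly ranked
    variable genes+proteins feed a 20-PC embedding, the SNN graph uses
    k = 20 neighbours, and differential expression requires 10% detection
    in each group, an absolute mean log-difference above 0.25 and BH FDR
    below 5%.
    """

    n_variable_features: int = 500
    n_pcs: int = 20
    snn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    cluster_resolution: float = 0.8
    min_genes_per_cell: int = 400
    de_min_detection: float = 0.10
    de_min_logdiff: float = 0.25
    de_fdr: float = 0.05
    gmm_components: int = 2
    lognorm_scale: float = 10000.0
    kmeans_k: int = 4
    posterior_threshold: float = 0.5
    hto_pseudocount: float = 1e-4
    min_hto_total: int = 10
    clr_pseudocount: float = 1.0
    loess_span: float = 0.3
    curve_span: float = 0.6
    curve_max_iter: int = 30
    curve_tol: float = 1e-4
    peak_bandwidth_frac: float = 0.1
    seeds: Seeds = field(default_factory=Seeds)

    def __post_init__(self) -> None:
        if isinstance(self.seeds, dict):
            self.seeds = Seeds(**self.seeds)
        for name in ("n_variable_features", "n_pcs", "snn_k",
                     "min_genes_per_cell", "gmm_components", "kmeans_k",
                     "curve_max_iter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("de_min_detection", "de_fdr", "posterior_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.lognorm_scale <= 0:
            raise ValueError("lognorm_scale must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)
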