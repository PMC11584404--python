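"""Run-wide configuration with YAML serialization.

Defaults are the production settings of the full pipeline: flat Dirichlet
prior (alpha = 1), a 1,000-step chain with 500-step burn-in and thinning 2,
pseudo_min = 0, genes kept when expressed in at least 4 spots, 6 equal-weight
neighbors, autocorrelation FDR 0.01, module FDR 0.05 with a 15-gene floor,
60% read subsampling repeated 100 times with a 0.8 consensus cutoff, marker
thresholds p < 0.01 and log2FC > 0.1, and top-100 benchmark marker sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # deconvolution
    alpha: float = 1.0
    chain_length: int = 1000
    burn_in: int = 500
    thinning: int = 2
    pseudo_min: float = 0.0
    min_spots_per_gene: int = 4
    # spot QC (auto-scaled down for shallow datasets, see pipeline)
    min_genes_per_spot: int = 1000
    min_umis_per_spot: int = 1000
    # spatial statistics
    k_neighbors: int = 6
    autocorr_fdr: float = 0.01
    module_fdr: float = 0.05
    min_gene_threshold: int = 15
    core_only: bool = True
    # consensus
    subsample_rate: float = 0.6
    n_subsamples: int = 100
    consensus_threshold: float = 0.8
    # markers
    marker_p_threshold: float = 0.01
    marker_fc_threshold: float = 0.1
    top_n_markers: int = 100
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not (0 < self.subsample_rate <= 1):
            raise ValueError("subsample_rate must be in (0, 1]")
        if self.n_subsamples < 2:
            raise ValueError("n_subsamples must be >= 2")
        if not (0 <= self.consensus_threshold <= 1):
            raise ValueError("consensus_threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
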