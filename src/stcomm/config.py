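"""Flat analysis configuration with the pipeline's tunable thresholds.

Every threshold printed in the workflow lives here with its default:
colocalization requires PCC > 0.06 at BH-adjusted p < 0.05, the regulon
co-activation network keeps CSI > 0.85, axis gene selection unions the top-20
PCC per section pattern, axis regulons need |PCC| > 1.5 x SD and max activity
> 0.2, progenitor-region scores are zeroed below z = 2.5, recovery-curve AUC
uses the top 5% of the gene ranking, and counts are log-normalized with a
scale factor of 10,000.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    min_pcc: float = 0.06       # colocalization edge: PCC strictly above this
    alpha: float = 0.05         # shared significance level (BH q / permutation p)
    csi_edge: float = 0.85      # regulon network: CSI strictly above this
    top_k: int = 20             # axis genes: top-k PCC per section pattern
    sd_mult: float = 1.5        # axis regulons: |PCC| > sd_mult * SD(PCCs)
    min_max_ras: float = 0.2    # axis regulons: max activity strictly above this
    z_min: float = 2.5          # z-score binarization cutoff
    top_frac: float = 0.05      # recovery-AUC max rank as a fraction of genes
    n_perm: int = 1000          # label permutations for communication p-values
    scale_factor: float = 10000.0  # log-normalization scale factor
    weight_threshold: float = 0.1  # default weight binarization cutoff
    kh: float = 0.5             # half-saturation of the communication score
    n_modules: int = 7          # regulon modules cut from the CSI dendrogram
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not -1 <= self.min_pcc <= 1:
            raise ValueError("min_pcc must be in [-1, 1]")
        if not 0 <= self.csi_edge <= 1:
            raise ValueError("csi_edge must be in [0, 1]")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must be in (0, 1]")
        if not 0 < self.weight_threshold < 1:
            raise ValueError("weight_threshold must be in (0, 1)")
        if self.top_k < 1 or self.n_modules < 2:
            raise ValueError("top_k must be >= 1 and n_modules >= 2")
        if self.n_perm < 0 or self.scale_factor <= 0:
            raise ValueError("n_perm must be >= 0 and scale_factor > 0")
        if self.sd_mult < 0 or self.kh <= 0:
            raise ValueError("sd_mult must be >= 0 and kh > 0")
        if not 0 <= self.min_max_ras <= 1:
            raise ValueError("min_max_ras must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)
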