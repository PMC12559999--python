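"""Analysis-wide thresholds and levels.

Defaults follow the study conditions this package targets: 95% UFBoot2 as the
strong-support threshold, the 95% ANI species threshold, NANUQ decision levels
alpha = 1e-6 (T3 test) and beta = 0.1 (star test), regression significance at
alpha = 0.01, and the SNV strain-heterogeneity filter (non-consensus allele
frequency >= 0.1 flags a locus; a genome with flagged loci in more than 20%
of its loci is dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    support_threshold: float = 95.0   # 0-100 UFBoot2 scale
    alpha_t3: float = 1e-6            # T3 (tree-fit) rejection level
    beta_star: float = 0.1            # star-tree non-rejection level
    ani_threshold: float = 95.0       # percent ANI for clustering
    regression_alpha: float = 0.01    # slope-test significance
    snv_freq_threshold: float = 0.1   # non-consensus allele frequency
    snv_taxon_fraction: float = 0.2   # flagged-locus fraction dropping a genome
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.support_threshold <= 100:
            raise ValueError("support_threshold must be in [0, 100]")
        for name in ("alpha_t3", "beta_star", "regression_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.ani_threshold <= 100:
            raise ValueError("ani_threshold must be in (0, 100]")
        for name in ("snv_freq_threshold", "snv_taxon_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from a YAML key-value file; unknown keys are rejected."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))
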