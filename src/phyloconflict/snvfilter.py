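"""Strain-heterogeneity filter on per-genome per-locus SNV summaries.

Metagenome-assembled genomes can carry traces of secondary strains.  A
(genome, locus) pair is flagged when the locus contains an SNV whose
non-consensus allele frequency reaches the configured threshold; flagged
loci are dropped from that genome, and a genome whose flagged fraction
exceeds the taxon-fraction threshold (strictly) is dropped outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AnalysisConfig

SNV_COLUMNS = ["genome", "locus", "snv_count", "max_freq"]


@dataclass
class SNVFilterResult:
    kept: set          # (genome, locus) pairs surviving the filter
    dropped_genomes: set
    flagged: set       # (genome, locus) pairs that triggered the frequency rule


def validate_snv_summary(snv: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNV_COLUMNS if c not in snv.columns]
    if missing:
        raise ValueError(f"SNV summary missing columns: {missing}")
    if snv.duplicated(subset=["genome", "locus"]).any():
        raise ValueError("SNV summary has duplicate (genome, locus) rows")
    if ((snv["max_freq"] < 0) | (snv["max_freq"] > 1)).any():
        raise ValueError("max_freq outside [0, 1]")
    if (snv["snv_count"] < 0).any():
        raise ValueError("negative snv_count")
    return snv


def filter_snv_sequences(snv: pd.DataFrame, cfg: AnalysisConfig) -> SNVFilterResult:
    """Apply the locus- and genome-level SNV filters.

    A locus is flagged iff max_freq >= cfg.snv_freq_threshold.  A genome is
    dropped iff its flagged fraction (over the loci it has rows for) is
    strictly greater than cfg.snv_taxon_fraction; all loci of a dropped
    genome leave the kept set.
    """
    snv = validate_snv_summary(snv)
    flagged_mask = snv["max_freq"] >= cfg.snv_freq_threshold
    flagged = set(map(tuple, snv.loc[flagged_mask, ["genome", "locus"]].itertuples(index=False)))

    frac = flagged_mask.groupby(snv["genome"]).mean()
    dropped = set(frac[frac > cfg.snv_taxon_fraction].index)

    keep_mask = ~flagged_mask & ~snv["genome"].isin(dropped)
    kept = set(map(tuple, snv.loc[keep_mask, ["genome", "locus"]].itertuples(index=False)))
    return SNVFilterResult(kept=kept, dropped_genomes=dropped, flagged=flagged)
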