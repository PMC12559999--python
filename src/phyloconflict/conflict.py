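"""Gene-tree vs species-tree conflict scoring.

Each gene tree is scored against each internal branch (bipartition) of the
species tree as one of five categories: strong support, weak support, strong
conflict, weak conflict, or missing.  The species bipartition is first
restricted to the taxa present in the gene tree; a restricted side with
fewer than two taxa cannot be evaluated and scores as missing.  "Strong"
means the relevant gene-tree split carries support at or above the
configured threshold (95 UFBoot2 by default); absent supports count as 0.

Per-branch tallies feed two products: the five-way proportions used for
pie-chart style summaries, and log-linear regressions of conflict
percentages on internode length, whose negative slopes are the signature of
coalescent (ILS-driven) conflict concentrating on short internodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .trees import (BranchRecord, Tree, bipartitions_compatible,
                    extract_bipartitions, informative_splits)


class Category(str, Enum):
    STRONG_SUPPORT = "strong_support"
    WEAK_SUPPORT = "weak_support"
    STRONG_CONFLICT = "strong_conflict"
    WEAK_CONFLICT = "weak_conflict"
    MISSING = "missing"


CATEGORIES = [c.value for c in Category]


def classify_gene_tree_vs_branch(gene: Tree, branch: BranchRecord,
                                 threshold: float = 95.0,
                                 _gene_splits=None) -> Category:
    """Score one gene tree against one species-tree branch.

    ``_gene_splits`` lets callers reuse the gene tree's restricted split
    dictionary across branches (see :func:`tally_conflicts`).
    """
    shared = gene.taxon_set & branch.bipartition.taxa
    restricted = branch.bipartition.restrict(shared)
    if restricted is None or not restricted.is_informative:
        return Category.MISSING
    if _gene_splits is None:
        _gene_splits = informative_splits(gene, restrict_to=branch.bipartition.taxa)
    # splits were computed on the shared taxon set already when reused
    if restricted in _gene_splits:
        sup = _gene_splits[restricted] or 0.0
        return Category.STRONG_SUPPORT if sup >= threshold else Category.WEAK_SUPPORT
    for split, sup in _gene_splits.items():
        if split.taxa != restricted.taxa:
            continue
        if not bipartitions_compatible(split, restricted) and (sup or 0.0) >= threshold:
            return Category.STRONG_CONFLICT
    return Category.WEAK_CONFLICT


@dataclass
class ConflictTally:
    """Per-branch five-way counts over a set of gene trees."""

    branches: list          # BranchRecord, in extract_bipartitions order
    counts: pd.DataFrame    # index: branch_id, columns: the five categories
    n_genes: int

    def proportions(self, include_missing: bool = True) -> pd.DataFrame:
        """Five-way (or four-way) proportions per branch.

        With ``include_missing`` the denominator is the full gene count
        (pie-chart convention); without it the denominator is the scored
        gene count (regression convention).
        """
        if include_missing:
            return self.counts.div(self.n_genes)
        scored = self.counts[CATEGORIES[:4]]
        denom = scored.sum(axis=1)
        return scored.div(denom.replace(0, np.nan), axis=0)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "n_genes", self.n_genes)
        return out


def tally_conflicts(species: Tree, genes: Sequence[Tree],
                    cfg: Optional[AnalysisConfig] = None) -> ConflictTally:
    """Score every gene tree against every internal species-tree branch."""
    cfg = cfg or AnalysisConfig()
    if len(species.tip_labels()) < 4:
        raise ValueError("species tree needs at least 4 tips")
    if not genes:
        raise ValueError("no gene trees supplied")
    branches = extract_bipartitions(species)
    species_taxa = species.taxon_set
    counts = {b.branch_id: dict.fromkeys(CATEGORIES, 0) for b in branches}
    for gene in genes:
        shared = gene.taxon_set & species_taxa
        gene_splits = informative_splits(gene, restrict_to=shared) if len(shared) >= 4 else {}
        for b in branches:
            restricted = b.bipartition.restrict(shared)
            if restricted is None or not restricted.is_informative:
                cat = Category.MISSING
            else:
                cat = _classify_restricted(restricted, gene_splits, cfg.support_threshold)
            counts[b.branch_id][cat.value] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index")[CATEGORIES]
    frame.index.name = "branch_id"
    frame = frame.loc[[b.branch_id for b in branches]]
    return ConflictTally(branches=branches, counts=frame, n_genes=len(genes))


def _classify_restricted(restricted, gene_splits, threshold) -> Category:
    # gene_splits are on the shared taxon set; restrict each to the
    # bipartition's taxa (identical here since restricted.taxa == shared)
    if restricted in gene_splits:
        sup = gene_splits[restricted] or 0.0
        return Category.STRONG_SUPPORT if sup >= threshold else Category.WEAK_SUPPORT
    strong = False
    for split, sup in gene_splits.items():
        if not bipartitions_compatible(split, restricted) and (sup or 0.0) >= threshold:
            strong = True
            break
    return Category.STRONG_CONFLICT if strong else Category.WEAK_CONFLICT


# ---------------------------------------------------------------------------
# Log-linear regression of conflict percentages on internode length
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    response: str
    slope: float
    intercept: float
    p_slope: float
    r_squared: float
    n: int


def fit_loglinear(xs: Sequence[float], ys: Sequence[float],
                  response: str = "percent") -> RegressionFit:
    """OLS of ``ys`` on the natural log of ``xs`` with a two-sided t-test on
    the slope.  ``xs`` are branch lengths (any positive time-like unit);
    ``ys`` are percentages (or any per-branch statistic)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be equal-length 1-D sequences")
    if len(xs) < 3:
        raise ValueError("need at least 3 points")
    if np.any(xs <= 0):
        bad = np.flatnonzero(xs <= 0)
        raise ValueError(f"nonpositive branch lengths at positions {bad.tolist()}")
    if np.ptp(ys) == 0:
        # constant response: flat fit, no evidence against zero slope
        return RegressionFit(response=response, slope=0.0, intercept=float(ys[0]),
                             p_slope=1.0, r_squared=0.0, n=len(xs))
    res = stats.linregress(np.log(xs), ys)
    return RegressionFit(
        response=response,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_slope=float(res.pvalue),
        r_squared=float(res.rvalue ** 2),
        n=len(xs),
    )


def conflict_regressions(tally: ConflictTally, lengths: dict,
                         include_missing: bool = False) -> list[RegressionFit]:
    """Fit one log-linear model per conflict category against branch length.

    ``lengths`` maps branch_id -> positive length (e.g. millions of years);
    branches without a length are skipped.  By default percentages use the
    scored-only denominator (missing excluded), the regression convention.
    """
    props = tally.proportions(include_missing=include_missing) * 100.0
    fits = []
    ids = [b.branch_id for b in tally.branches if b.branch_id in lengths]
    xs = [lengths[i] for i in ids]
    cats = CATEGORIES if include_missing else CATEGORIES[:4]
    for cat in cats:
        ys = props.loc[ids, cat].to_numpy()
        ok = ~np.isnan(ys)
        fits.append(fit_loglinear(np.asarray(xs)[ok], ys[ok], response=cat))
    return fits
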