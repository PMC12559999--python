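"""Quartet concordance analysis: counts, star and T3 tests, NANUQ distances.

For every 4-taxon subset, each gene tree containing all four taxa displays
exactly one of three resolved topologies (or none, if the restriction is a
star).  Under the multispecies coalescent on a resolved species quartet the
expected topology frequencies are (1 - (2/3)e^-t, (1/3)e^-t, (1/3)e^-t), so
the counts let us test, per quartet:

* the *star* hypothesis — all three frequencies equal 1/3 (internal branch
  length 0) — via a multinomial likelihood-ratio test against the
  unrestricted alternative (chi-squared, 2 df);
* the *T3* hypothesis — the frequencies arose from SOME resolved species
  quartet under the MSC, i.e. lie on the curve {major >= 1/3, two equal
  minors} — via a likelihood-ratio test (chi-squared, 1 df, with a
  parametric-bootstrap fallback near the center of the simplex where the
  asymptotics degrade).

Rejecting T3 at a small alpha flags the quartet as reticulate (network-like);
failing to reject the star at beta flags it as star-like; everything else is
tree-like.  The per-quartet decisions are then folded into the NANUQ
inter-taxon distance whose splits graph visualizes network structure.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .trees import Tree, informative_splits

# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

#: pairings of positions (with taxa sorted) keyed by count slot:
#: slot 0 = t0t1|t2t3, slot 1 = t0t2|t1t3, slot 2 = t0t3|t1t2
_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass
class QuartetRecord:
    taxa: tuple                 # canonically sorted 4-tuple
    counts: tuple               # (n1, n2, n3) keyed by _PAIRINGS
    n_unresolved: int = 0

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def concordance_factors(self) -> tuple:
        n = self.n
        if n == 0:
            return (math.nan,) * 3
        return tuple(c / n for c in self.counts)


def count_quartet_topologies(genes: Sequence[Tree], taxa,
                             sample_size: Optional[int] = None,
                             seed: int = 0,
                             max_exhaustive: int = 500_000) -> list[QuartetRecord]:
    """Count the displayed topology of each 4-subset of ``taxa`` in each
    gene tree.

    All quartets are enumerated when their number is at most
    ``max_exhaustive`` (and ``sample_size`` is None); otherwise
    ``sample_size`` quartets are drawn uniformly without replacement with
    the given seed.  Gene trees missing any of a quartet's taxa do not count
    toward that quartet; unresolved restrictions are tracked separately.
    """
    taxa = sorted(frozenset(taxa))
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    n_total = math.comb(len(taxa), 4)
    if sample_size is None and n_total > max_exhaustive:
        sample_size = max_exhaustive
    if sample_size is not None and sample_size < n_total:
        rng = np.random.default_rng(seed)
        all_q = list(itertools.combinations(taxa, 4))
        idx = rng.choice(len(all_q), size=sample_size, replace=False)
        quartets = [all_q[i] for i in sorted(idx)]
    else:
        quartets = list(itertools.combinations(taxa, 4))

    counts = {q: [0, 0, 0] for q in quartets}
    unresolved = dict.fromkeys(quartets, 0)
    taxon_set = frozenset(taxa)
    for gene in genes:
        present = gene.taxon_set & taxon_set
        if len(present) < 4:
            continue
        splits = list(informative_splits(gene, restrict_to=present).keys())
        sides = [s.side_a for s in splits]
        for q in quartets:
            if not all(t in present for t in q):
                continue
            slot = _displayed_slot(q, sides)
            if slot is None:
                unresolved[q] += 1
            else:
                counts[q][slot] += 1
    return [QuartetRecord(taxa=q, counts=tuple(counts[q]), n_unresolved=unresolved[q])
            for q in quartets]


def _displayed_slot(q, sides) -> Optional[int]:
    """Which of the three pairings a gene tree's splits display for quartet
    ``q`` (taxa sorted), or None if unresolved."""
    for side in sides:
        inside = [t in side for t in q]
        if sum(inside) != 2:
            continue
        pair = tuple(i for i in range(4) if inside[i])
        for slot, (p1, p2) in enumerate(_PAIRINGS):
            if pair == p1 or pair == p2:
                return slot
    return None


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def _lr_statistic(counts: np.ndarray, probs: np.ndarray) -> float:
    """2 sum n_i log(n_i / (n p_i)); zero-count terms contribute 0."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    stat = 0.0
    for c, p in zip(counts, probs):
        if c > 0:
            stat += 2.0 * c * math.log(c / (n * p))
    return max(0.0, stat)


def star_test(q: QuartetRecord, bootstrap: int = 0, seed: int = 0) -> float:
    """P-value for H0: the three topology frequencies all equal 1/3
    (star quartet).  Chi-squared with 2 df by default; a parametric
    bootstrap p-value is returned when ``bootstrap`` > 0."""
    n = q.n
    if n == 0:
        return math.nan
    counts = np.asarray(q.counts, dtype=float)
    stat = _lr_statistic(counts, np.full(3, 1.0 / 3.0))
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = rng.multinomial(n, [1 / 3] * 3, size=bootstrap)
        boot = _lr_statistics_batch(reps, np.full(3, 1.0 / 3.0))
        return float((np.count_nonzero(boot >= stat - 1e-12) + 1) / (bootstrap + 1))
    return float(stats.chi2.sf(stat, df=2))


def _t3_mle(counts: np.ndarray) -> np.ndarray:
    """Constrained MLE on the T3 model {p_major >= 1/3, equal minors}, with
    the major coordinate taken at the (first) largest count."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    j = int(np.argmax(counts))
    p_major = max(counts[j] / n, 1.0 / 3.0)
    p = np.full(3, (1.0 - p_major) / 2.0)
    p[j] = p_major
    return p


def t3_test(q: QuartetRecord, bootstrap: int = 10_000, seed: int = 0,
            force_bootstrap: Optional[bool] = None) -> float:
    """P-value for H0: the counts arose from some resolved species quartet
    under the MSC (T3 model).

    Chi-squared with 1 df by default.  Near the center of the simplex
    (|p_major_hat - 1/3| < 2/sqrt(n)) the chi-squared approximation is
    unreliable and a parametric bootstrap at the constrained MLE is used
    instead; ``force_bootstrap`` overrides the automatic choice.
    """
    n = q.n
    if n == 0:
        return math.nan
    counts = np.asarray(q.counts, dtype=float)
    p_hat = _t3_mle(counts)
    stat = _lr_statistic(counts, p_hat)
    near_center = abs(p_hat.max() - 1.0 / 3.0) < 2.0 / math.sqrt(n)
    use_boot = near_center if force_bootstrap is None else force_bootstrap
    if use_boot and bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = rng.multinomial(n, p_hat, size=bootstrap)
        boot = np.empty(bootstrap)
        for i, rep in enumerate(reps):
            boot[i] = _lr_statistic(rep, _t3_mle(rep))
        return float((np.count_nonzero(boot >= stat - 1e-12) + 1) / (bootstrap + 1))
    return float(stats.chi2.sf(stat, df=1))


def _lr_statistics_batch(reps: np.ndarray, probs: np.ndarray) -> np.ndarray:
    reps = np.asarray(reps, dtype=float)
    n = reps.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = 2.0 * reps * np.log(reps / (n * probs))
    terms = np.where(reps > 0, terms, 0.0)
    return np.clip(terms.sum(axis=1), 0.0, None)


# ---------------------------------------------------------------------------
# Classification and summary
# ---------------------------------------------------------------------------

@dataclass
class QuartetTestResult:
    taxa: tuple
    p_star: float
    p_t3: float
    classification: str           # treelike | reticulate | starlike | nodata
    topology: Optional[tuple]     # ((a,b),(c,d)) split pairs when treelike


SENSITIVITY_GRID = (1e-2, 1e-3, 1e-5, 1e-6)


def classify_quartets(records: Sequence[QuartetRecord], alpha: float = 1e-6,
                      beta: float = 0.1,
                      t3_seed: int = 0) -> tuple[list[QuartetTestResult], dict]:
    """Per-quartet decisions plus a summary of class fractions.

    Decision rule: reticulate iff p_T3 < alpha; otherwise star-like iff
    p_star >= beta; otherwise tree-like with the majority topology (ties in
    the majority count are classified star-like, conservatively).  The
    summary also reports the tree-like/reticulate fractions across the
    sensitivity grid of alpha values.
    """
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must be in (0, 1)")
    results = []
    p_t3s = []
    for i, q in enumerate(records):
        if q.n == 0:
            results.append(QuartetTestResult(q.taxa, math.nan, math.nan, "nodata", None))
            p_t3s.append(math.nan)
            continue
        p_star = star_test(q)
        p_t3 = t3_test(q, seed=t3_seed + i)
        p_t3s.append(p_t3)
        if p_t3 < alpha:
            cls, topo = "reticulate", None
        elif p_star >= beta:
            cls, topo = "starlike", None
        else:
            counts = q.counts
            m = max(counts)
            if list(counts).count(m) > 1:
                cls, topo = "starlike", None
            else:
                slot = counts.index(m)
                (i1, i2), (i3, i4) = _PAIRINGS[slot]
                topo = ((q.taxa[i1], q.taxa[i2]), (q.taxa[i3], q.taxa[i4]))
                cls = "treelike"
        results.append(QuartetTestResult(q.taxa, p_star, p_t3, cls, topo))

    scored = [r for r in results if r.classification != "nodata"]
    n_scored = len(scored)
    summary = {
        "n_quartets": len(results),
        "n_scored": n_scored,
        "alpha": alpha,
        "beta": beta,
        "frac_treelike": _frac(scored, "treelike"),
        "frac_reticulate": _frac(scored, "reticulate"),
        "frac_starlike": _frac(scored, "starlike"),
        "grid": {},
    }
    for a in SENSITIVITY_GRID:
        retic = sum(1 for r, p in zip(results, p_t3s)
                    if r.classification != "nodata" and p < a)
        summary["grid"][a] = {
            "frac_reticulate": retic / n_scored if n_scored else math.nan,
            "frac_tree_or_star": 1 - retic / n_scored if n_scored else math.nan,
        }
    return results, summary


def _frac(scored, cls):
    if not scored:
        return math.nan
    return sum(1 for r in scored if r.classification == cls) / len(scored)


# ---------------------------------------------------------------------------
# NANUQ distance
# ---------------------------------------------------------------------------

def nanuq_distance_matrix(results: Sequence[QuartetTestResult], taxa,
                          unresolved_weight: float = 0.5):
    """NANUQ-style inter-taxon distance.

    For each scored quartet: a tree-like quartet with split ab|cd
    contributes 0 to the cherry pairs (a,b) and (c,d) and 1 to the four
    cross pairs; a reticulate or star-like quartet contributes
    ``unresolved_weight`` to all six pairs.  Quartets with no data are
    skipped with a warning.

    Returns (labels, matrix) with a symmetric zero-diagonal numpy array.
    """
    labels = sorted(frozenset(taxa))
    index = {t: i for i, t in enumerate(labels)}
    d = np.zeros((len(labels), len(labels)))
    n_missing = 0
    expected = math.comb(len(labels), 4)
    seen = 0
    for r in results:
        if r.classification == "nodata":
            n_missing += 1
            continue
        seen += 1
        quad = [index[t] for t in r.taxa]
        if r.classification == "treelike":
            (a, b), (c, d_) = r.topology
            ia, ib, ic, id_ = index[a], index[b], index[c], index[d_]
            for x, y in ((ia, ic), (ia, id_), (ib, ic), (ib, id_)):
                d[x, y] += 1.0
                d[y, x] += 1.0
        else:
            for x, y in itertools.combinations(quad, 2):
                d[x, y] += unresolved_weight
                d[y, x] += unresolved_weight
    if seen < expected:
        warnings.warn(
            f"{expected - seen} of {expected} quartets unscored; distance is partial",
            stacklevel=2,
        )
    return labels, d


def write_nexus_distances(labels, matrix, path=None) -> str:
    """Nexus DISTANCES block (lower-triangular) for splits-network viewers."""
    n = len(labels)
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"  DIMENSIONS NTAX={n};",
        "  TAXLABELS",
    ]
    lines += [f"    {_nexus_label(t)}" for t in labels]
    lines += ["  ;", "END;", "", "BEGIN DISTANCES;",
              f"  DIMENSIONS NTAX={n};",
              "  FORMAT TRIANGLE=LOWER DIAGONAL LABELS=LEFT;",
              "  MATRIX"]
    for i, t in enumerate(labels):
        row = " ".join(f"{matrix[i, j]:.6g}" for j in range(i + 1))
        lines.append(f"    {_nexus_label(t)} {row}")
    lines += ["  ;", "END;", ""]
    text = "\n".join(lines)
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text


def _nexus_label(label: str) -> str:
    if any(ch in label for ch in " ()[]{};,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label
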