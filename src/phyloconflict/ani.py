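"""ANI-based genome clustering and gap analysis.

Pairwise average nucleotide identity (ANI) tables, as produced by FastANI,
report each direction of a genome pair separately and slightly
asymmetrically.  This module symmetrizes them (mean of reciprocal values),
clusters genomes at a threshold (single-linkage: connected components of the
ANI >= threshold graph; 95% is the conventional bacterial species cutoff),
scans the pairwise-value distribution for gaps (candidate species
boundaries, like the one centred near 86% ANI in *Nostoc*), and lays values
out in species-tree tip order for dot-plot rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .trees import Tree

ANI_COLUMNS = ["query", "reference", "ani", "frag_mapped", "frag_total"]


def read_fastani_tsv(path) -> pd.DataFrame:
    """Read a FastANI-style TSV (query, reference, ANI%, mapped, total)."""
    df = pd.read_csv(path, sep="\t", header=None, names=ANI_COLUMNS,
                     comment="#", skip_blank_lines=True)
    if df["ani"].dtype == object:  # header line present
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
    return df[ANI_COLUMNS[: len(df.columns)]]


def symmetrize_ani(table: pd.DataFrame) -> pd.DataFrame:
    """Genome x genome matrix: mean of reciprocal directions, diagonal 100.

    One-direction-only pairs keep their single value with a warning;
    reciprocal asymmetries above 1 percentage point warn but are averaged.
    """
    if ((table["ani"] <= 0) | (table["ani"] > 100)).any():
        raise ValueError("ANI values must lie in (0, 100]")
    genomes = sorted(set(table["query"]) | set(table["reference"]))
    idx = {g: i for i, g in enumerate(genomes)}
    n = len(genomes)
    vals = np.full((n, n), np.nan)
    for q, r, ani in table[["query", "reference", "ani"]].itertuples(index=False):
        vals[idx[q], idx[r]] = ani
    one_way = 0
    big_asym = 0
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = vals[i, j], vals[j, i]
            if np.isnan(a) and np.isnan(b):
                continue
            if np.isnan(a) or np.isnan(b):
                one_way += 1
                m = a if not np.isnan(a) else b
            else:
                if abs(a - b) > 1.0:
                    big_asym += 1
                m = (a + b) / 2.0
            out[i, j] = out[j, i] = m
    if one_way:
        warnings.warn(f"{one_way} genome pairs present in one direction only", stacklevel=2)
    if big_asym:
        warnings.warn(f"{big_asym} genome pairs with reciprocal ANI asymmetry > 1 point",
                      stacklevel=2)
    return pd.DataFrame(out, index=genomes, columns=genomes)


@dataclass
class ANIClusterSet:
    assignments: dict           # genome -> cluster id (integers from 1)
    threshold: float

    def clusters(self) -> list[frozenset]:
        by_id: dict[int, set] = {}
        for g, c in self.assignments.items():
            by_id.setdefault(c, set()).add(g)
        return [frozenset(by_id[c]) for c in sorted(by_id)]


def cluster_genomes(matrix: pd.DataFrame, threshold: float = 95.0,
                    linkage: str = "single") -> ANIClusterSet:
    """Threshold clustering of the symmetrized ANI matrix.

    ``single`` linkage (default) takes connected components of the graph
    with an edge wherever ANI >= threshold; ``complete`` requires every
    within-cluster pair to reach the threshold (greedy agglomeration, for
    comparison only).  Clusters are numbered by their smallest member label.
    """
    genomes = list(matrix.index)
    g = nx.Graph()
    g.add_nodes_from(genomes)
    arr = matrix.to_numpy()
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            if not np.isnan(arr[i, j]) and arr[i, j] >= threshold:
                g.add_edge(genomes[i], genomes[j])
    if linkage == "single":
        comps = [sorted(c) for c in nx.connected_components(g)]
    elif linkage == "complete":
        comps = [sorted(c) for c in nx.find_cliques(g)]
        # greedy max-clique cover: assign each genome to its first clique
        comps.sort(key=lambda c: (-len(c), c))
        assigned: set = set()
        cover = []
        for c in comps:
            keep = [x for x in c if x not in assigned]
            if keep:
                cover.append(keep)
                assigned.update(keep)
        comps = cover
    else:
        raise ValueError("linkage must be 'single' or 'complete'")
    comps.sort(key=lambda c: c[0])
    assignments = {}
    for i, comp in enumerate(comps, start=1):
        for genome in comp:
            assignments[genome] = i
    return ANIClusterSet(assignments=assignments, threshold=threshold)


@dataclass
class GapInterval:
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def center(self) -> float:
        return (self.lower + self.upper) / 2.0

    def contains(self, value: float) -> bool:
        return self.lower < value < self.upper


def detect_ani_gaps(values, min_width: float = 0.5,
                    resolution: float = 0.1) -> list[GapInterval]:
    """Maximal empty open intervals of the pairwise ANI distribution.

    Found by scanning sorted consecutive values (exact; equivalent to a grid
    scan at any resolution); only gaps at least ``min_width`` wide are
    reported, with bounds rounded outward-safe to ``resolution`` decimals
    for display.  Sorted by lower bound.
    """
    if min_width <= 0:
        raise ValueError("min_width must be positive")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    vals = np.sort(np.unique(np.asarray(list(values), dtype=float)))
    if len(vals) < 2:
        raise ValueError("need at least 2 ANI values")
    gaps = []
    diffs = np.diff(vals)
    for i in np.flatnonzero(diffs >= min_width):
        gaps.append(GapInterval(float(vals[i]), float(vals[i + 1])))
    return gaps


def tree_ordered_ani_table(tree: Tree, matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (focal, partner, ani) rows with focal genomes in tree
    tip (preorder) order — the dot-plot layout of the ANI mosaic figure."""
    tips = tree.tip_labels()
    missing = [t for t in tips if t not in matrix.index]
    if missing:
        raise ValueError(f"tree tips absent from ANI matrix: {missing}")
    rows = []
    for focal in tips:
        for partner in tips:
            if focal == partner:
                continue
            rows.append((focal, partner, matrix.loc[focal, partner]))
    return pd.DataFrame(rows, columns=["focal", "partner", "ani"])
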