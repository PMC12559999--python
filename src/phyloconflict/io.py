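"""File-level interfaces: newick tree files, gene-tree sets, and the TSV
tables the pipeline consumes (SNV summaries, FastANI output, specimen
tables)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .snvfilter import SNV_COLUMNS
from .cooccur import SPECIMEN_COLUMNS
from .trees import Tree, parse_newick, write_newick


def read_tree(path, unit_tag: str = "none") -> Tree:
    """Read a single-tree newick file."""
    return parse_newick(Path(path).read_text(), unit_tag=unit_tag)


def read_gene_trees(path, unit_tag: str = "none") -> list[Tree]:
    """Read a one-tree-per-line newick file."""
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line, unit_tag=unit_tag))
    return trees


def write_trees(trees, path) -> None:
    Path(path).write_text("".join(write_newick(t) + "\n" for t in trees))


def read_snv_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in SNV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNV TSV missing columns: {missing}")
    return df[SNV_COLUMNS]


def read_specimen_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"specimen TSV missing columns: {missing}")
    df.loc[df["partner"] == "", "partner"] = None
    return df[SPECIMEN_COLUMNS]
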