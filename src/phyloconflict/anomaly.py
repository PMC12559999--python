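"""Anomaly-zone detection on a coalescent-unit species tree.

A pair of adjacent internal branches (parent length x, descendant length y,
both in coalescent units) lies in the anomaly zone when y < a(x), where

    a(x) = log[ 2/3 + (3 e^{2x} - 2) / (18 (e^{3x} - e^{2x})) ]

(natural log).  In that region the most probable gene-tree topology differs
from the species-tree topology, the defining pathology of rapid radiations
under the multispecies coalescent.  a is strictly decreasing with
a(x) -> log(2/3) < 0 as x -> infinity, so long parent branches can never be
anomalous; a(x) -> +infinity as x -> 0+.

The scan treats the two root-incident edges of a rooted binary tree as one
unrooted branch (quartet-based species-tree methods estimate coalescent-unit
lengths on the unrooted topology), and clusters the anomalous internodes
into maximal connected sets of adjacent branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .trees import BranchRecord, Tree, extract_bipartitions

# Beyond this x, e^{3x} would overflow comfort; a(x) is already far below 0.
_X_SHORT_CIRCUIT = 30.0


def anomaly_boundary(x: float) -> float:
    """The anomaly-zone boundary a(x) for a parent internal branch of length
    ``x`` coalescent units; a descendant internal branch of length y is in
    the zone iff y < a(x)."""
    if x <= 0:
        raise ValueError("a(x) requires x > 0 (singular at 0)")
    if x > _X_SHORT_CIRCUIT:
        return math.log(2.0 / 3.0)
    e2x = math.exp(2.0 * x)
    e3x = math.exp(3.0 * x)
    return math.log(2.0 / 3.0 + (3.0 * e2x - 2.0) / (18.0 * (e3x - e2x)))


@dataclass
class AnomalyPair:
    parent_id: str
    child_id: str
    x: float
    y: float
    a_of_x: float
    in_zone: bool


@dataclass
class AnomalyCluster:
    index: int
    branch_ids: frozenset


def _branch_map(species: Tree) -> tuple[list[BranchRecord], dict]:
    """Branch records plus a node -> record map using the merged-root
    convention (both root children of a binary root map to the same
    record)."""
    records = extract_bipartitions(species)
    by_bottom: dict[int, BranchRecord] = {}
    for rec in records:
        by_bottom[id(rec._bottom)] = rec
        # merged root branch: _top is the sibling root child
        if rec._top is not None and rec._top.parent is species.root and \
                rec._bottom.parent is species.root:
            by_bottom[id(rec._top)] = rec
    return records, by_bottom


def detect_anomaly_pairs(species: Tree) -> list[AnomalyPair]:
    """One pair per adjacency between an internal branch and an internal
    descendant branch; terminal branches never participate."""
    if species.length_unit != "coalescent":
        raise ValueError("anomaly scan requires coalescent-unit branch lengths")
    records, by_bottom = _branch_map(species)
    pairs: list[AnomalyPair] = []
    for rec in records:
        child_node = rec._bottom
        parent_node = child_node.parent
        if parent_node is None or parent_node is species.root:
            continue
        parent_rec = by_bottom.get(id(parent_node))
        if parent_rec is None or parent_rec is rec:
            continue
        x = parent_rec.length_cu
        y = rec.length_cu
        if x is None:
            raise ValueError(f"branch {parent_rec.branch_id} lacks a coalescent-unit length")
        if y is None:
            raise ValueError(f"branch {rec.branch_id} lacks a coalescent-unit length")
        if x > 0:
            a = anomaly_boundary(x)
            in_zone = y < a
        else:
            # limit x -> 0+: a(x) -> +infinity, every descendant is anomalous
            a = math.inf
            in_zone = True
        pairs.append(AnomalyPair(parent_rec.branch_id, rec.branch_id, x, y, a, in_zone))
    return pairs


def cluster_anomaly_internodes(pairs: list[AnomalyPair], species: Tree) -> list[AnomalyCluster]:
    """Maximal connected sets of adjacent internal branches appearing in any
    in-zone pair, numbered deterministically by preorder position."""
    records, _ = _branch_map(species)
    order = {rec.branch_id: i for i, rec in enumerate(records)}
    endpoints = {}
    for rec in records:
        endpoints[rec.branch_id] = {id(rec._top), id(rec._bottom)}
    flagged = set()
    for p in pairs:
        if p.in_zone:
            flagged.update((p.parent_id, p.child_id))
    g = nx.Graph()
    g.add_nodes_from(flagged)
    flagged_list = sorted(flagged, key=order.get)
    for i, a in enumerate(flagged_list):
        for b in flagged_list[i + 1:]:
            if endpoints[a] & endpoints[b]:
                g.add_edge(a, b)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(order[b] for b in c))
    return [AnomalyCluster(index=i + 1, branch_ids=c) for i, c in enumerate(comps)]
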