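"""Synthetic-data generators.

Everything downstream of raw data in this package can be exercised with the
generators here:

* :func:`simulate_gene_trees` — gene trees under the multispecies coalescent
  (MSC) on a species tree with internal branch lengths in coalescent units,
  one haploid lineage per species (population sizes are absorbed into the
  coalescent-unit scale).  Within a species-tree branch of length *t*, the
  *k* extant lineages coalesce pairwise at rate 1 per pair; unfinished
  lineages are handed to the parent population, and the root population has
  unlimited time.
* :func:`apply_estimation_error` — a stand-in for gene-tree estimation noise:
  short internal branches are more likely to be randomly rearranged (NNI) and
  receive lower pseudo-supports, reproducing the empirical pattern that short
  internodes accumulate weakly supported conflict.
* :func:`simulate_ani_table` — pairwise ANI from an ultrametric dated tree
  via a monotone divergence-time -> ANI map, with noise, reciprocal-pair
  asymmetry, and an optional imposed gap in the ANI distribution.
* :func:`simulate_specimen_table` — lichen specimen tables (site, cyanobiont
  OTU, fungal partner) with a tunable elevation of partner sharing between
  co-occurring specimens, mimicking local vertical transmission of the
  symbiont.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import Node, Tree


# ---------------------------------------------------------------------------
# MSC gene-tree simulation
# ---------------------------------------------------------------------------

def expected_quartet_cf(t: float) -> tuple[float, float, float]:
    """Exact MSC quartet concordance factors for internal branch length t
    (coalescent units): (1 - (2/3)e^-t, (1/3)e^-t, (1/3)e^-t)."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    minor = math.exp(-t) / 3.0
    return (1.0 - 2.0 * minor, minor, minor)


def _node_heights(species: Tree) -> dict:
    """Height above the latest tip, taking each tip's height as 0."""
    heights: dict[int, float] = {}
    for node in species.postorder():
        if node.is_leaf:
            heights[id(node)] = 0.0
        else:
            heights[id(node)] = max(
                heights[id(c)] + (c.length or 0.0) for c in node.children
            )
    return heights


def simulate_gene_trees(species: Tree, n_loci: int, seed: int) -> list[Tree]:
    """Draw ``n_loci`` gene trees under the MSC on ``species``.

    The species tree must be rooted with every internal branch length present
    in coalescent units.  Gene trees carry coalescent-unit branch lengths for
    inspection; topology is what downstream analyses consume.
    """
    if species.length_unit != "coalescent":
        raise ValueError("species tree must carry coalescent-unit lengths")
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    for node in species.preorder():
        if node is not species.root and not node.is_leaf and node.length is None:
            below = sorted(l.label for l in _subtree_leaves(node))
            raise ValueError(f"internal branch above clade {below} has no length")

    rng = np.random.default_rng(seed)
    heights = _node_heights(species)
    post = [n for n in species.postorder()]
    out = []
    for _ in range(n_loci):
        out.append(_simulate_one(species, post, heights, rng))
    return out


def _subtree_leaves(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _simulate_one(species: Tree, post: Sequence[Node], heights: dict,
                  rng: np.random.Generator) -> Tree:
    # lineages[id(species node)] = [(gene Node, time the lineage was created)]
    lineages: dict[int, list] = {}
    for snode in post:
        if snode.is_leaf:
            # one haploid lineage sampled per species, at time 0
            lineages[id(snode)] = [(Node(label=snode.label, length=0.0), 0.0)]
            continue
        active = []
        for c in snode.children:
            active.extend(lineages.pop(id(c)))
        is_root = snode is species.root
        duration = math.inf if is_root else snode.length
        t0 = heights[id(snode)]
        elapsed = 0.0
        while len(active) > 1:
            k = len(active)
            wait = rng.exponential(2.0 / (k * (k - 1)))
            if elapsed + wait > duration:
                break
            elapsed += wait
            i, j = (int(x) for x in rng.choice(k, size=2, replace=False))
            a, ta = active[i]
            b, tb = active[j]
            coal = t0 + elapsed
            a.length = coal - ta
            b.length = coal - tb
            parent = Node(length=0.0)
            parent.add_child(a)
            parent.add_child(b)
            active = [active[m] for m in range(k) if m not in (i, j)]
            active.append((parent, coal))
        lineages[id(snode)] = active
    (root_node, _), = lineages[id(species.root)]
    root_node.length = None
    return Tree(root_node, length_unit="coalescent")


def observed_quartet_cf(gene_trees: Sequence[Tree], quartet: Sequence[str]):
    """Observed concordance factors for one quartet across gene trees.

    Returns (cf1, cf2, cf3, n) keyed like the quartet module: with sorted
    taxa (t0, t1, t2, t3), cf1 counts t0t1|t2t3, cf2 counts t0t2|t1t3,
    cf3 counts t0t3|t1t2.
    """
    from .quartets import count_quartet_topologies

    recs = count_quartet_topologies(list(gene_trees), frozenset(quartet))
    rec = recs[0]
    n = rec.n
    if n == 0:
        return (math.nan, math.nan, math.nan, 0)
    return (rec.counts[0] / n, rec.counts[1] / n, rec.counts[2] / n, n)


# ---------------------------------------------------------------------------
# Estimation-error model
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """Topology-estimation error and pseudo-support model.

    Per internal branch, the probability of a random NNI rearrangement is
    ``base_nni_prob * exp(-length / length_scale)`` — short branches are the
    ones gene-tree estimation gets wrong.  Pseudo-supports (0-100) are drawn
    around a mean that rises with the original branch length,
    ``100 * (1 - exp(-length / support_scale))``, damped by
    ``perturbed_support_factor`` on branches involved in an NNI, plus
    Gaussian noise, clipped to [0, 100].
    """

    base_nni_prob: float = 0.4
    length_scale: float = 1.0
    support_scale: float = 0.5
    support_noise_sd: float = 15.0
    perturbed_support_factor: float = 0.45

    def __post_init__(self):
        if not 0 <= self.base_nni_prob <= 1:
            raise ValueError("base_nni_prob must be in [0, 1]")
        if self.length_scale <= 0 or self.support_scale <= 0:
            raise ValueError("length scales must be positive")
        if self.support_noise_sd < 0:
            raise ValueError("support_noise_sd must be nonnegative")
        if not 0 <= self.perturbed_support_factor <= 1:
            raise ValueError("perturbed_support_factor must be in [0, 1]")

    def nni_prob(self, length: float) -> float:
        return self.base_nni_prob * math.exp(-length / self.length_scale)

    def mean_support(self, length: float, perturbed: bool) -> float:
        mean = 100.0 * (1.0 - math.exp(-length / self.support_scale))
        if perturbed:
            mean *= self.perturbed_support_factor
        return mean


def apply_estimation_error(tree: Tree, model: ErrorModel, seed: int) -> Tree:
    """Perturb a gene tree with random NNIs and attach pseudo-supports."""
    rng = np.random.default_rng(seed)
    out = tree.copy()
    # candidate edges: internal, non-root child whose parent has >= 2 children
    perturbed_ids: set[int] = set()
    for node in list(out.preorder()):
        if node is out.root or node.is_leaf:
            continue
        parent = node.parent
        if parent is None or len(node.children) < 2 or len(parent.children) < 2:
            continue
        length = node.length if node.length is not None else 0.0
        if rng.random() < model.nni_prob(length):
            _nni(node, rng)
            perturbed_ids.add(id(node))
    for node in out.preorder():
        if node is out.root or node.is_leaf:
            continue
        length = node.length if node.length is not None else 0.0
        mean = model.mean_support(length, id(node) in perturbed_ids)
        sup = mean + rng.normal(0.0, model.support_noise_sd)
        node.support = float(min(100.0, max(0.0, sup)))
    return out


def _nni(node: Node, rng: np.random.Generator) -> None:
    """Nearest-neighbour interchange across the edge above ``node``:
    swap one of the node's child subtrees with one of its siblings,
    choosing uniformly between the two alternative configurations."""
    parent = node.parent
    siblings = [c for c in parent.children if c is not node]
    sib = siblings[rng.integers(len(siblings))]
    child = node.children[rng.integers(len(node.children))]
    si = parent.children.index(sib)
    ci = node.children.index(child)
    parent.children[si], node.children[ci] = child, sib
    child.parent, sib.parent = parent, node


# ---------------------------------------------------------------------------
# ANI simulation
# ---------------------------------------------------------------------------

@dataclass
class ANISimParams:
    """Divergence-time -> ANI map with noise and an optional imposed gap.

    ``anchors`` are (time_My, expected ANI percent) pairs, monotone
    decreasing in ANI; expected ANI between a pair of genomes is the
    piecewise-linear interpolation at their divergence time (flat beyond the
    last anchor).  Values landing inside ``gap`` are redrawn.
    """

    anchors: Sequence[tuple[float, float]] = (
        (0.0, 100.0), (50.0, 96.0), (150.0, 92.0),
        (300.0, 88.0), (450.0, 84.0), (750.0, 78.0),
    )
    noise_sd: float = 0.4
    asymmetry_sd: float = 0.03
    gap: Optional[tuple[float, float]] = None
    max_resample: int = 1000

    def __post_init__(self):
        times = [a[0] for a in self.anchors]
        anis = [a[1] for a in self.anchors]
        if sorted(times) != list(times) or len(set(times)) != len(times):
            raise ValueError("anchor times must be strictly increasing")
        if any(anis[i + 1] >= anis[i] for i in range(len(anis) - 1)):
            raise ValueError("anchor ANI values must be strictly decreasing")
        if any(not 0 < a <= 100 for a in anis):
            raise ValueError("anchor ANI values must be in (0, 100]")
        if self.gap is not None and self.gap[0] >= self.gap[1]:
            raise ValueError("gap must be (lower, upper) with lower < upper")

    def expected_ani(self, time_my: float) -> float:
        times = np.array([a[0] for a in self.anchors])
        anis = np.array([a[1] for a in self.anchors])
        return float(np.interp(time_my, times, anis))


def _divergence_times(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Pairwise divergence times (age of the MRCA) on an ultrametric tree."""
    heights = _node_heights(tree)
    depths = {}
    root_height = heights[id(tree.root)]
    for leaf in tree.leaves():
        d = 0.0
        n = leaf
        while n.parent is not None:
            d += n.length or 0.0
            n = n.parent
        depths[leaf.label] = d
    vals = list(depths.values())
    if max(vals) - min(vals) > 1e-6 * max(1.0, root_height):
        raise ValueError("tree is not ultrametric; cannot map times to ANI")
    tips = tree.tip_labels()
    index = {t: i for i, t in enumerate(tips)}
    tmat = np.zeros((len(tips), len(tips)))
    # MRCA ages via recursive leaf-set merge
    leafsets = {}
    for node in tree.postorder():
        if node.is_leaf:
            leafsets[id(node)] = [node.label]
        else:
            groups = [leafsets[id(c)] for c in node.children]
            age = heights[id(node)]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            tmat[index[a], index[b]] = age
                            tmat[index[b], index[a]] = age
            leafsets[id(node)] = [x for g in groups for x in g]
    return tips, tmat


def simulate_ani_table(tree: Tree, params: ANISimParams, seed: int) -> pd.DataFrame:
    """FastANI-style long table (query, reference, ani, fragments) from a
    dated ultrametric tree; both directions emitted with small asymmetry."""
    if tree.length_unit != "time_My":
        raise ValueError("ANI simulation expects a tree dated in millions of years")
    rng = np.random.default_rng(seed)
    tips, tmat = _divergence_times(tree)
    rows = []
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            mu = params.expected_ani(tmat[i, j])
            val = _draw_outside_gap(mu, params, rng)
            for q, r in ((tips[i], tips[j]), (tips[j], tips[i])):
                v = val + rng.normal(0.0, params.asymmetry_sd)
                v = min(100.0, v)
                if params.gap is not None and params.gap[0] < v < params.gap[1]:
                    lo, hi = params.gap
                    v = lo if abs(v - lo) <= abs(v - hi) else hi
                rows.append((q, r, v, 1000, 1100))
    return pd.DataFrame(rows, columns=["query", "reference", "ani", "frag_mapped", "frag_total"])


def _draw_outside_gap(mu: float, params: ANISimParams, rng) -> float:
    for _ in range(params.max_resample):
        v = min(100.0, mu + rng.normal(0.0, params.noise_sd))
        if params.gap is None or not (params.gap[0] < v < params.gap[1]):
            return v
    lo, hi = params.gap
    return lo if abs(mu - lo) <= abs(mu - hi) else hi


# ---------------------------------------------------------------------------
# Specimen-table simulation
# ---------------------------------------------------------------------------

@dataclass
class SpecimenSimParams:
    """Co-occurrence generator for lichen specimen tables.

    ``partner_pools`` maps each cyanobiont OTU to the fungal partner labels
    it can associate with (pools may overlap between OTUs — that is what
    makes cross-OTU sharing possible).  ``sharing_elevation`` is the
    probability that a specimen copies the fungal partner of a co-occurring
    earlier specimen instead of drawing fresh from its pool; 0 makes partner
    choice independent of co-occurrence.
    """

    n_sites: int = 50
    specimens_per_otu: dict = field(default_factory=lambda: {"V": 120, "XLII": 60})
    partner_pools: dict = field(
        default_factory=lambda: {
            "V": [f"P{i}" for i in range(8)],
            "XLII": [f"P{i}" for i in range(5)],
        }
    )
    sharing_elevation: float = 0.0

    def __post_init__(self):
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not self.specimens_per_otu or any(v <= 0 for v in self.specimens_per_otu.values()):
            raise ValueError("specimen counts must be positive")
        for otu in self.specimens_per_otu:
            pool = self.partner_pools.get(otu)
            if not pool:
                raise ValueError(f"empty partner pool for OTU {otu!r}")
        if not 0 <= self.sharing_elevation <= 1:
            raise ValueError("sharing_elevation must be in [0, 1]")


def simulate_specimen_table(params: SpecimenSimParams, seed: int) -> pd.DataFrame:
    """Specimen table (specimen, site, otu, partner) honouring the configured
    counts exactly."""
    rng = np.random.default_rng(seed)
    records = []
    sites = [f"site{i:03d}" for i in range(params.n_sites)]
    by_site: dict[str, list] = {s: [] for s in sites}
    k = 0
    order = []
    for otu, n in params.specimens_per_otu.items():
        order.extend([otu] * n)
    rng.shuffle(order)
    for otu in order:
        site = sites[rng.integers(params.n_sites)]
        pool = params.partner_pools[otu]
        partner = None
        if params.sharing_elevation > 0 and by_site[site]:
            if rng.random() < params.sharing_elevation:
                donors = [p for p in by_site[site] if p in pool]
                if donors:
                    partner = donors[rng.integers(len(donors))]
        if partner is None:
            partner = pool[rng.integers(len(pool))]
        sid = f"spec{k:05d}"
        k += 1
        records.append((sid, site, otu, partner))
        by_site[site].append(partner)
    return pd.DataFrame(records, columns=["specimen", "site", "otu", "partner"])
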