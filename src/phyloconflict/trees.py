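"""Phylogenetic data model: newick I/O, bipartition algebra, tree restriction.

Trees are stored as a light node structure (children lists, branch length,
internal-node support on the 0-100 UFBoot2 scale) tagged with the unit of the
branch lengths (coalescent units, millions of years, substitutions per site,
or none).  Parsing is delegated to dendropy; everything downstream — split
extraction, restriction to a taxon subset, split compatibility — operates on
this structure directly, because those operations are the substance of the
conflict and anomaly analyses.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy

LENGTH_UNITS = ("coalescent", "time_My", "subs_per_site", "none")


class NewickParseError(ValueError):
    """Malformed newick input (unbalanced parentheses, duplicate tips, ...)."""


class Node:
    """A tree node; a tip iff it has no children.

    ``length`` is the length of the branch subtending this node (toward the
    root); ``support`` is only meaningful on internal nodes.
    """

    __slots__ = ("label", "length", "support", "children", "parent", "_depths")

    def __init__(self, label=None, length=None, support=None):
        self.label: Optional[str] = label
        self.length: Optional[float] = length
        self.support: Optional[float] = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length}, sup={self.support})"


class Tree:
    """Rooted tree container with a branch-length unit tag."""

    def __init__(self, root: Node, length_unit: str = "none", rooted: bool = True):
        if length_unit not in LENGTH_UNITS:
            raise ValueError(f"unknown length unit {length_unit!r}")
        self.root = root
        self.length_unit = length_unit
        self.rooted = rooted
        self._validate()

    # -- traversal -----------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        """Tip labels in preorder (left-to-right) order."""
        return [n.label for n in self.leaves()]

    @property
    def taxon_set(self) -> frozenset:
        return frozenset(self.tip_labels())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        labels = self.tip_labels()
        if not labels:
            raise ValueError("tree has no tips")
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        for n in self.preorder():
            if n.length is not None and n.length < 0:
                raise ValueError(f"negative branch length on {n.label or 'internal node'}")
            if n.support is not None and not (0 <= n.support <= 100):
                raise ValueError(f"support {n.support} outside [0, 100]")

    # -- copying -------------------------------------------------------

    def copy(self) -> "Tree":
        def _clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for c in node.children:
                new.add_child(_clone(c))
            return new

        return Tree(_clone(self.root), self.length_unit, self.rooted)

    # -- distances (used by tests and the ANI dot-plot ordering) --------

    def tip_distance_matrix(self) -> dict:
        """Pairwise tip-to-tip path lengths; missing lengths count as 0."""
        dist: dict = {}
        for node in self.postorder():
            if node.is_leaf:
                node_depths = {node.label: 0.0}
            else:
                node_depths = {}
                child_maps = []
                for c in node.children:
                    cm = {t: d + (c.length or 0.0) for t, d in c._depths.items()}
                    child_maps.append(cm)
                for i in range(len(child_maps)):
                    for j in range(i + 1, len(child_maps)):
                        for a, da in child_maps[i].items():
                            for b, db in child_maps[j].items():
                                dist[frozenset((a, b))] = da + db
                    node_depths.update(child_maps[i])
                node_depths.update(child_maps[-1])
            node._depths = node_depths  # type: ignore[attr-defined]
        for node in self.preorder():
            if hasattr(node, "_depths"):
                del node._depths
        return dist

    def __repr__(self):  # pragma: no cover
        return f"Tree({len(self.tip_labels())} tips, unit={self.length_unit})"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, unit_tag: str = "none") -> Tree:
    """Parse a single newick statement into a :class:`Tree`.

    Internal-node labels that parse as numbers are interpreted as branch
    supports.  Supports on a 0-1 scale (all numeric labels <= 1) are rescaled
    to 0-100 with a warning.  Square-bracket comments are ignored and quoted
    labels are honoured (dendropy dialect).
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc

    def _convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
        else:
            node = Node(label=None, length=dnode.edge.length)
            raw = dnode.label
            if raw is not None:
                try:
                    node.support = float(raw)
                except ValueError:
                    node.label = raw  # a named clade, not a support
            for child in dnode.child_nodes():
                node.add_child(_convert(child))
        return node

    root = _convert(dtree.seed_node)
    supports = [n.support for n in _iter_nodes(root) if n.support is not None]
    if supports and max(supports) <= 1.0:
        warnings.warn("supports look 0-1 scaled; rescaling to 0-100", stacklevel=2)
        for n in _iter_nodes(root):
            if n.support is not None:
                n.support *= 100.0
    tree = Tree(root, unit_tag)
    _suppress_unifurcations(tree.root)
    return tree


def _iter_nodes(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _format_float(x: float) -> str:
    s = f"{x:.10g}"
    return s


def write_newick(tree: Tree) -> str:
    """Serialize a tree; inverse of :func:`parse_newick` for topology,
    lengths (to printed precision) and supports."""
    if tree is None or not tree.tip_labels():
        raise ValueError("refusing to write an empty tree")

    def _fmt(node: Node) -> str:
        if node.is_leaf:
            out = _quote(node.label)
        else:
            inner = ",".join(_fmt(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = _format_float(node.support)
            elif node.label:
                label = _quote(node.label)
            out = f"({inner}){label}"
        if node.length is not None:
            out += f":{_format_float(node.length)}"
        return out

    return _fmt(tree.root) + ";"


_NEEDS_QUOTE = set(" ()[]{}:;,'\"")


def _quote(label: Optional[str]) -> str:
    if label is None:
        return ""
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of a taxon set into two disjoint nonempty sides."""

    side_a: frozenset
    side_b: frozenset

    def __post_init__(self):
        if not self.side_a or not self.side_b:
            raise ValueError("bipartition sides must be nonempty")
        if self.side_a & self.side_b:
            raise ValueError("bipartition sides must be disjoint")
        a, b = sorted((self.side_a, self.side_b), key=lambda s: tuple(sorted(s)))
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)

    @property
    def taxa(self) -> frozenset:
        return self.side_a | self.side_b

    @property
    def is_informative(self) -> bool:
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    @property
    def key(self):
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))

    def restrict(self, taxa: Iterable) -> Optional["Bipartition"]:
        """Induced split on a taxon subset, or None if a side empties."""
        taxa = frozenset(taxa)
        a = self.side_a & taxa
        b = self.side_b & taxa
        if not a or not b:
            return None
        return Bipartition(a, b)

    def __str__(self):  # pragma: no cover
        return "{%s | %s}" % (",".join(sorted(self.side_a)), ",".join(sorted(self.side_b)))


def bipartitions_compatible(b1: Bipartition, b2: Bipartition) -> bool:
    """Standard split compatibility: some pairwise side intersection is empty."""
    if b1.taxa != b2.taxa:
        raise ValueError("bipartitions are over different taxon sets")
    return (
        not (b1.side_a & b2.side_a)
        or not (b1.side_a & b2.side_b)
        or not (b1.side_b & b2.side_a)
        or not (b1.side_b & b2.side_b)
    )


@dataclass
class BranchRecord:
    """An internal branch of the (unrooted) species tree.

    Carries the split it induces plus its lengths in coalescent units (x, y
    of the anomaly-zone scan live here) and/or millions of years, and its
    support.  ``_top``/``_bottom`` are the rooted-tree endpoints of the edge,
    kept for adjacency work; for the merged root branch of a rooted binary
    tree they are the two root children.
    """

    branch_id: str
    bipartition: Bipartition
    length_cu: Optional[float] = None
    length_my: Optional[float] = None
    support: Optional[float] = None
    _top: Optional[Node] = field(default=None, repr=False)
    _bottom: Optional[Node] = field(default=None, repr=False)


def _branch_length_for_unit(tree: Tree, length: Optional[float]):
    cu = length if tree.length_unit == "coalescent" else None
    my = length if tree.length_unit == "time_My" else None
    return cu, my


def extract_bipartitions(tree: Tree) -> list[BranchRecord]:
    """One record per internal branch of the unrooted topology.

    For a rooted binary tree the two root-incident edges describe the same
    unrooted branch; they are merged into a single record whose length is the
    sum of the two edge lengths.  Fewer than 4 tips yields no records.
    """
    if len(tree.tip_labels()) < 4:
        return []
    taxa = tree.taxon_set
    leafsets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset((node.label,))
        else:
            leafsets[id(node)] = frozenset().union(*(leafsets[id(c)] for c in node.children))

    records: list[BranchRecord] = []
    seen: set = set()
    root = tree.root
    merged_root = len(root.children) == 2
    idx = 0
    for node in tree.preorder():
        if node is root or node.is_leaf:
            continue
        below = leafsets[id(node)]
        bip = Bipartition(below, taxa - below)
        if not bip.is_informative or bip.key in seen:
            continue
        seen.add(bip.key)
        length = node.length
        support = node.support
        top, bottom = node.parent, node
        if merged_root and node.parent is root:
            sib = next(c for c in root.children if c is not node)
            if length is not None or sib.length is not None:
                length = (length or 0.0) + (sib.length or 0.0)
            support = node.support if node.support is not None else sib.support
            top, bottom = sib, node
        cu, my = _branch_length_for_unit(tree, length)
        records.append(
            BranchRecord(f"b{idx}", bip, length_cu=cu, length_my=my, support=support,
                         _top=top, _bottom=bottom)
        )
        idx += 1
    return records


# ---------------------------------------------------------------------------
# Restriction
# ---------------------------------------------------------------------------

def restrict_tree(tree: Tree, taxa: Iterable) -> Tree:
    """Induced subtree on ``taxa``: other tips removed, degree-2 nodes
    suppressed with their incident branch lengths summed (supports of
    suppressed nodes are discarded)."""
    taxa = frozenset(taxa)
    unknown = taxa - tree.taxon_set
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    if not taxa:
        raise ValueError("cannot restrict to an empty taxon set")

    out = tree.copy()

    def _prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if node.label in taxa else None
        kept = []
        for c in node.children:
            k = _prune(c)
            if k is not None:
                kept.append(k)
        if not kept:
            return None
        node.children = []
        for k in kept:
            node.add_child(k)
        return node

    root = _prune(out.root)
    if root is None:  # cannot happen: taxa nonempty and validated
        raise ValueError("restriction removed every tip")
    root.parent = None
    _suppress_unifurcations(root)
    while len(root.children) == 1:
        child = root.children[0]
        child.parent = None
        child.length = None
        child.support = None
        root = child
    return Tree(root, tree.length_unit, tree.rooted)


def _suppress_unifurcations(root: Node) -> None:
    """Splice out internal degree-2 nodes, summing branch lengths."""
    stack = [root]
    while stack:
        node = stack.pop()
        i = 0
        while i < len(node.children):
            child = node.children[i]
            while len(child.children) == 1:
                grand = child.children[0]
                if grand.length is not None or child.length is not None:
                    grand.length = (grand.length or 0.0) + (child.length or 0.0)
                grand.parent = node
                node.children[i] = grand
                child = grand
            i += 1
        stack.extend(node.children)


# ---------------------------------------------------------------------------
# Splits with supports (shared by conflict and quartet scoring)
# ---------------------------------------------------------------------------

def informative_splits(tree: Tree, restrict_to: Optional[frozenset] = None) -> dict:
    """Informative splits of ``tree``, optionally induced on a taxon subset.

    Returns ``{Bipartition: support}``; when several edges induce the same
    split after restriction the maximum support is kept, and supports absent
    on the tree are reported as None.
    """
    taxa = tree.taxon_set if restrict_to is None else (tree.taxon_set & frozenset(restrict_to))
    splits: dict = {}
    leafsets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset((node.label,)) & taxa
        else:
            below = frozenset().union(*(leafsets[id(c)] for c in node.children))
            leafsets[id(node)] = below
            if node is tree.root:
                continue
            a = below
            b = taxa - below
            if len(a) < 2 or len(b) < 2:
                continue
            bip = Bipartition(a, b)
            sup = node.support
            if bip not in splits:
                splits[bip] = sup
            elif sup is not None and (splits[bip] is None or sup > splits[bip]):
                splits[bip] = sup
    return splits


def displays(tree: Tree, bip: Bipartition) -> bool:
    """True iff the tree restricted to the split's taxa displays the split."""
    return bip in informative_splits(tree, restrict_to=bip.taxa)
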