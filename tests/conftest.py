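import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("repro", derandomize=True, deadline=None)
    settings.load_profile("repro")
except ImportError:  # pragma: no cover
    pass

from phyloconflict import Tree, parse_newick
from phyloconflict.trees import Node


def caterpillar(internal_lengths, unit="coalescent", tip_length=1.0,
                root_arm=2.0, prefix="T"):
    """Rooted caterpillar: ((((T0,T1):l0,T2):l1,...):root_arm, Tlast).

    ``internal_lengths[i]`` is the branch above the clade containing the
    first i+2 tips; the deepest cherry gets internal_lengths[0].
    """
    tips = [f"{prefix}{i}" for i in range(len(internal_lengths) + 3)]
    nwk = f"({tips[0]}:{tip_length},{tips[1]}:{tip_length})"
    for i, ln in enumerate(internal_lengths):
        nwk = f"({nwk}:{ln},{tips[i + 2]}:{tip_length})"
    nwk = f"({nwk}:{root_arm},{tips[-1]}:{tip_length});"
    return parse_newick(nwk, unit)


def random_resolved_tree(labels, rng, with_lengths=True, with_supports=False):
    """Random rooted binary tree by sequential random attachment."""
    labels = list(labels)
    rng.shuffle(labels)
    nodes = [Node(label=labels[0]), Node(label=labels[1])]
    root = Node()
    root.add_child(nodes[0])
    root.add_child(nodes[1])
    edges = [nodes[0], nodes[1]]  # nodes whose parent edge can be split
    for lab in labels[2:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node()
        tip = Node(label=lab)
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(tip)
        edges.extend([mid, tip])
    for n in list(iter_nodes(root)):
        if n is not root and with_lengths:
            n.length = float(np.round(rng.uniform(0.05, 2.0), 4))
        if n is not root and not n.is_leaf and with_supports:
            n.support = float(np.round(rng.uniform(0, 100), 1))
    return Tree(root, "coalescent" if with_lengths else "none")


def iter_nodes(root):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def rooted_topology_key(tree):
    """Frozenset of clade leaf-sets — equality iff same rooted topology."""
    sets = []

    def rec(n):
        if n.is_leaf:
            return frozenset([n.label])
        s = frozenset().union(*[rec(c) for c in n.children])
        sets.append(s)
        return s

    rec(tree.root)
    return frozenset(sets)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
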