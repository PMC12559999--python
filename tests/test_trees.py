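import numpy as np
import pandas as pd
import pytest

from phyloconflict import (AnalysisConfig, Bipartition, NewickParseError,
                           bipartitions_compatible, extract_bipartitions,
                           filter_snv_sequences, parse_newick, restrict_tree,
                           write_newick)
from phyloconflict.trees import informative_splits

from conftest import random_resolved_tree


class TestParsing:
    def test_basic_lengths(self):
        t = parse_newick("((A:1,B:1):0.5,C:1.5);")
        assert sorted(t.tip_labels()) == ["A", "B", "C"]
        internal = [n for n in t.internal_nodes() if n is not t.root]
        assert len(internal) == 1 and internal[0].length == 0.5

    def test_supports_attach_to_internal_nodes(self):
        t = parse_newick("((A,B)95:0.2,(C,D)80:0.1);")
        sups = sorted(n.support for n in t.internal_nodes() if n.support is not None)
        assert sups == [80.0, 95.0]

    @pytest.mark.parametrize("bad", ["((A,B);", "", "((A,B),(A,C));"])
    def test_malformed_or_duplicate_raises(self, bad):
        with pytest.raises((NewickParseError, ValueError)):
            parse_newick(bad)

    def test_zero_one_supports_rescaled_with_warning(self):
        with pytest.warns(UserWarning, match="rescaling"):
            t = parse_newick("((A,B)0.95:0.2,(C,D)0.8:0.1);")
        sups = sorted(n.support for n in t.internal_nodes() if n.support is not None)
        assert sups == [80.0, 95.0]

    def test_comments_and_quoted_labels(self):
        t = parse_newick("(('sp one':1,B:1)[a comment]:0.5,C:1.5);")
        assert "sp one" in t.tip_labels()


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_trees_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(rng.integers(4, 12))]
        t = random_resolved_tree(labels, rng, with_lengths=True, with_supports=True)
        t2 = parse_newick(write_newick(t), t.length_unit)
        assert write_newick(t2) == write_newick(t)
        assert informative_splits(t2).keys() == informative_splits(t).keys()

    def test_no_lengths_no_colons(self):
        t = parse_newick("((A,B),C);")
        assert ":" not in write_newick(t)

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            write_newick(None)


class TestBipartitions:
    def test_single_informative_split(self):
        recs = extract_bipartitions(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        assert len(recs) == 1
        assert recs[0].bipartition == Bipartition(frozenset("AB"), frozenset("CD"))

    def test_caterpillar_five_tips(self):
        recs = extract_bipartitions(parse_newick("((((A,B),C),D),E);"))
        assert len(recs) == 2

    def test_star_tree_none(self):
        assert extract_bipartitions(parse_newick("(A,B,C,D,E);")) == []

    def test_fewer_than_four_tips_empty(self):
        assert extract_bipartitions(parse_newick("((A,B),C);")) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_resolved_tree_has_n_minus_3_records(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 15))
        t = random_resolved_tree([f"x{i}" for i in range(n)], rng)
        assert len(extract_bipartitions(t)) == n - 3

    def test_merged_root_branch_length_is_sum(self):
        recs = extract_bipartitions(parse_newick("((A:1,B:1):0.4,(C:1,D:1):0.2);", "coalescent"))
        assert recs[0].length_cu == pytest.approx(0.6)


class TestCompatibility:
    def test_identical_compatible(self):
        b = Bipartition(frozenset("AB"), frozenset("CD"))
        assert bipartitions_compatible(b, b)

    def test_crossing_incompatible(self):
        b1 = Bipartition(frozenset("AB"), frozenset("CD"))
        b2 = Bipartition(frozenset("AC"), frozenset("BD"))
        assert not bipartitions_compatible(b1, b2)

    def test_nested_compatible(self):
        b1 = Bipartition(frozenset("AB"), frozenset("CDE"))
        b2 = Bipartition(frozenset("ABC"), frozenset("DE"))
        assert bipartitions_compatible(b1, b2)

    def test_different_taxon_sets_error(self):
        b1 = Bipartition(frozenset("AB"), frozenset("CD"))
        b2 = Bipartition(frozenset("AB"), frozenset("CE"))
        with pytest.raises(ValueError):
            bipartitions_compatible(b1, b2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_agrees_with_tree_existence_oracle(self, n_taxa, rng):
        """Two splits are compatible iff some binary tree displays both;
        verified by exhaustive enumeration of unrooted topologies."""
        from itertools import combinations

        taxa = [chr(65 + i) for i in range(n_taxa)]
        splits = []
        for k in range(2, n_taxa - 1):
            for side in combinations(taxa, k):
                b = Bipartition(frozenset(side), frozenset(taxa) - frozenset(side))
                if b not in splits:
                    splits.append(b)
        all_trees = _enumerate_unrooted(taxa)
        for b1 in splits:
            for b2 in splits:
                displayed = any(b1 in t and b2 in t for t in all_trees)
                assert displayed == bipartitions_compatible(b1, b2), (b1, b2)


def _enumerate_unrooted(taxa):
    """All unrooted binary topologies as sets of informative splits."""
    from phyloconflict.trees import Tree
    from phyloconflict.trees import Node

    def build(labels):
        if len(labels) == 3:
            root = Node()
            for lab in labels:
                root.add_child(Node(label=lab))
            yield root
            return
        lab = labels[-1]
        for base in build(labels[:-1]):
            for target in _edges(base):
                parent = target.parent
                mid = Node()
                tip = Node(label=lab)
                i = parent.children.index(target)
                parent.children[i] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(tip)
                yield base
                # undo
                mid.children.remove(target)
                target.parent = parent
                parent.children[i] = target

    def _edges(root):
        out = []
        stack = list(root.children)
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    result = []
    for top in build(list(taxa)):
        t = Tree(_clone(top), "none")
        result.append(set(informative_splits(t).keys()))
    return result


def _clone(node):
    from phyloconflict.trees import Node
    new = Node(node.label, node.length, node.support)
    for c in node.children:
        new.add_child(_clone(c))
    return new


class TestRestriction:
    def test_path_lengths_summed_through_suppressed_nodes(self):
        t = parse_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        r = restrict_tree(t, {"A", "C", "D"})
        dist = r.tip_distance_matrix()
        full = t.tip_distance_matrix()
        for pair in [frozenset("AC"), frozenset("AD"), frozenset("CD")]:
            assert dist[pair] == pytest.approx(full[pair])
        # A hangs off the root through the suppressed (A,B) ancestor: 1+1
        a = next(n for n in r.leaves() if n.label == "A")
        assert a.length == pytest.approx(2.0)

    def test_restriction_to_all_tips_is_identity(self):
        t = parse_newick("((A:1,B:1)90:0.5,(C:1,D:1)80:0.2);")
        r = restrict_tree(t, t.taxon_set)
        assert write_newick(r) == write_newick(t)

    def test_two_tip_restriction_uninformative(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        r = restrict_tree(t, {"A", "C"})
        assert extract_bipartitions(r) == []

    def test_unknown_taxon_error_names_it(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="Z"):
            restrict_tree(t, {"A", "Z"})

    @pytest.mark.parametrize("seed", range(3))
    def test_pairwise_distances_preserved(self, seed):
        rng = np.random.default_rng(seed)
        t = random_resolved_tree([f"x{i}" for i in range(10)], rng)
        keep = set(list(t.taxon_set)[:5])
        r = restrict_tree(t, keep)
        full = t.tip_distance_matrix()
        sub = r.tip_distance_matrix()
        for pair, d in sub.items():
            assert d == pytest.approx(full[pair]), pair


class TestSNVFilter:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["genome", "locus", "snv_count", "max_freq"])

    def test_locus_flagged_at_threshold(self):
        rows = [("g1", "L1", 2, 0.05), ("g1", "L2", 3, 0.15)]
        rows += [("g1", f"L{i}", 1, 0.01) for i in range(3, 11)]
        res = filter_snv_sequences(self._frame(rows), AnalysisConfig())
        assert ("g1", "L1") in res.kept and ("g1", "L2") not in res.kept
        assert res.flagged == {("g1", "L2")}
        assert res.dropped_genomes == set()

    def test_genome_dropped_above_20_percent(self):
        rows = [("g", f"L{i}", 1, 0.5 if i < 21 else 0.01) for i in range(100)]
        res = filter_snv_sequences(self._frame(rows), AnalysisConfig())
        assert res.dropped_genomes == {"g"}
        assert res.kept == set()

    def test_genome_kept_at_exactly_20_percent(self):
        rows = [("g", f"L{i}", 1, 0.5 if i < 20 else 0.01) for i in range(100)]
        res = filter_snv_sequences(self._frame(rows), AnalysisConfig())
        assert res.dropped_genomes == set()
        assert len(res.kept) == 80

    def test_bad_frequency_rejected(self):
        snv = self._frame([("g", "L", 1, 1.5)])
        with pytest.raises(ValueError):
            filter_snv_sequences(snv, AnalysisConfig())
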