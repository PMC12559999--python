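import itertools
import math

import numpy as np
import pytest
from scipy import stats

from phyloconflict import (classify_quartets, count_quartet_topologies,
                           nanuq_distance_matrix, parse_newick, restrict_tree,
                           star_test, t3_test, write_nexus_distances)
from phyloconflict.quartets import QuartetRecord, QuartetTestResult, _t3_mle

from conftest import random_resolved_tree


def q(counts, taxa=("a", "b", "c", "d")):
    return QuartetRecord(taxa=tuple(taxa), counts=tuple(counts))


class TestCounting:
    def test_all_genes_same_topology(self):
        genes = [parse_newick("((a,b),(c,d));")] * 3
        rec = count_quartet_topologies(genes, "abcd")[0]
        assert rec.counts == (3, 0, 0) and rec.n == 3

    def test_gene_missing_taxon_excluded(self):
        genes = [parse_newick("((a,b),(c,d));"), parse_newick("((a,b),c);")]
        rec = count_quartet_topologies(genes, "abcd")[0]
        assert rec.n == 1

    def test_unresolved_restriction_tracked_separately(self):
        genes = [parse_newick("(a,b,c,d);")]
        rec = count_quartet_topologies(genes, "abcd")[0]
        assert rec.n == 0 and rec.n_unresolved == 1

    def test_taxon_order_invariance(self):
        genes = [parse_newick("((a,c),(b,d));")]
        r1 = count_quartet_topologies(genes, "abcd")[0]
        r2 = count_quartet_topologies(genes, "dcba")[0]
        assert r1 == r2

    def test_concordance_factors_sum_to_one(self):
        rng = np.random.default_rng(0)
        genes = [random_resolved_tree(list("abcdefgh"), rng) for _ in range(30)]
        for rec in count_quartet_topologies(genes, "abcdefgh"):
            assert sum(rec.concordance_factors) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_tree_restriction_oracle(self, seed):
        """Brute force: restrict every gene tree to every quartet and read
        the displayed topology off the restricted tree."""
        rng = np.random.default_rng(200 + seed)
        taxa = list("abcdefgh")
        genes = [random_resolved_tree(taxa[: rng.integers(5, 9)], rng)
                 for _ in range(15)]
        records = {r.taxa: r for r in count_quartet_topologies(genes, taxa)}
        for quartet in itertools.combinations(sorted(taxa), 4):
            counts = [0, 0, 0]
            for gene in genes:
                if not set(quartet) <= gene.taxon_set:
                    continue
                sub = restrict_tree(gene, set(quartet))
                cherries = [frozenset(c.label for c in n.children)
                            for n in sub.internal_nodes()
                            if all(c.is_leaf for c in n.children)
                            and len(n.children) == 2]
                pair = next((c for c in cherries
                             if c != frozenset(quartet)), None)
                if pair is None:
                    continue
                t0 = quartet[0]
                if t0 in pair:
                    other = next(iter(pair - {t0}))
                else:
                    # pair is the complementary cherry; t0 pairs with the rest
                    other = next(iter(set(quartet) - pair - {t0}))
                counts[quartet.index(other) - 1] += 1
            assert tuple(counts) == records[quartet].counts, quartet


class TestStarTest:
    def test_balanced_counts_give_p_one(self):
        assert star_test(q((100, 100, 100))) == pytest.approx(1.0)

    def test_extreme_counts_reject(self):
        stat = 2 * 300 * math.log(3)
        assert star_test(q((300, 0, 0))) == pytest.approx(
            float(stats.chi2.sf(stat, 2)), abs=1e-12)
        assert star_test(q((300, 0, 0))) < 1e-6

    def test_moderate_counts_match_direct_formula(self):
        counts = (40, 30, 30)
        n = 100
        stat = 2 * sum(c * math.log(3 * c / n) for c in counts)
        assert star_test(q(counts)) == pytest.approx(float(stats.chi2.sf(stat, 2)))

    def test_no_data_marker(self):
        assert math.isnan(star_test(q((0, 0, 0))))


class TestT3Test:
    def test_counts_on_model_give_p_one(self):
        assert t3_test(q((50, 25, 25))) == pytest.approx(1.0)

    def test_center_belongs_to_model(self):
        assert t3_test(q((100, 100, 100))) == pytest.approx(1.0, abs=0.01)

    def test_mle_respects_major_floor(self):
        p = _t3_mle(np.array([30, 40, 30]))
        assert p[1] == pytest.approx(0.4)
        p = _t3_mle(np.array([34, 33, 33]))
        assert p[0] == pytest.approx(0.34)
        p = _t3_mle(np.array([20, 30, 50]))
        assert p[2] == pytest.approx(0.5) and p[0] == p[1] == pytest.approx(0.25)

    def test_off_model_counts_checked_against_bootstrap_oracle(self):
        """(40, 40, 20) is near the center: the automatic bootstrap must be
        within Monte-Carlo error of an independently coded oracle."""
        counts = (40, 40, 20)
        p_auto = t3_test(q(counts), bootstrap=10_000, seed=5)
        # independent oracle: plain numpy loop, MLE re-derived inline
        rng = np.random.default_rng(99)
        n = sum(counts)

        def mle(c):
            j = int(np.argmax(c))
            pm = max(c[j] / n, 1 / 3)
            p = [(1 - pm) / 2] * 3
            p[j] = pm
            return p

        def lr(c, p):
            return 2 * sum(ci * math.log(ci / (n * pi))
                           for ci, pi in zip(c, p) if ci > 0)

        obs = lr(counts, mle(counts))
        assert obs > 0
        reps = rng.multinomial(n, mle(counts), size=10_000)
        boot = np.array([lr(r, mle(r)) for r in reps])
        p_oracle = (np.sum(boot >= obs - 1e-12) + 1) / (10_001)
        assert p_auto == pytest.approx(p_oracle, abs=0.03)

    def test_chi2_close_to_bootstrap_away_from_center(self):
        for counts in [(150, 80, 70), (180, 60, 60), (140, 90, 70)]:
            rec = q(counts)
            p_chi = t3_test(rec, force_bootstrap=False)
            p_boot = t3_test(rec, bootstrap=10_000, seed=11, force_bootstrap=True)
            assert p_chi == pytest.approx(p_boot, abs=0.02)

    def test_no_data_marker(self):
        assert math.isnan(t3_test(q((0, 0, 0))))


class TestClassification:
    def test_exact_model_counts_treelike(self):
        res, _ = classify_quartets([q((600, 200, 200))], alpha=1e-6, beta=0.1)
        assert res[0].classification == "treelike"
        assert res[0].topology == (("a", "b"), ("c", "d"))

    def test_center_counts_starlike(self):
        res, _ = classify_quartets([q((200, 200, 200))], alpha=1e-6, beta=0.1)
        assert res[0].classification == "starlike"

    def test_majority_tie_is_starlike(self):
        res, _ = classify_quartets([q((240, 240, 120))], alpha=1e-10, beta=1e-4)
        assert res[0].classification == "starlike"

    def test_summary_reports_sensitivity_grid(self):
        _, summary = classify_quartets([q((600, 200, 200)), q((200, 200, 200))])
        assert set(summary["grid"]) == {1e-2, 1e-3, 1e-5, 1e-6}


class TestNanuqDistance:
    def test_single_resolved_quartet(self):
        res = [QuartetTestResult(("a", "b", "c", "d"), 0.01, 0.5, "treelike",
                                 (("a", "b"), ("c", "d")))]
        labels, d = nanuq_distance_matrix(res, "abcd")
        i = {t: k for k, t in enumerate(labels)}
        assert d[i["a"], i["b"]] == 0 and d[i["c"], i["d"]] == 0
        for x, y in (("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")):
            assert d[i[x], i[y]] == 1

    def test_all_starlike_constant_off_diagonal(self):
        results = [
            QuartetTestResult(taxa, 0.9, 0.5, "starlike", None)
            for taxa in itertools.combinations("abcde", 4)
        ]
        labels, d = nanuq_distance_matrix(results, "abcde")
        off = d[~np.eye(5, dtype=bool)]
        # each pair occurs in C(3,2)=3 of the 5 quartets
        assert np.allclose(off, 0.5 * 3)

    def test_five_taxon_brute_force_sum(self, rng):
        genes = [random_resolved_tree(list("abcde"), rng) for _ in range(40)]
        recs = count_quartet_topologies(genes, "abcde")
        results, _ = classify_quartets(recs, alpha=1e-6, beta=0.1)
        labels, d = nanuq_distance_matrix(results, "abcde")
        i = {t: k for k, t in enumerate(labels)}
        for x, y in itertools.combinations("abcde", 2):
            expected = 0.0
            for r in results:
                if x not in r.taxa or y not in r.taxa:
                    continue
                if r.classification == "treelike":
                    (a, b), (c, dd) = r.topology
                    if {x, y} in ({a, b}, {c, dd}):
                        pass
                    else:
                        expected += 1.0
                else:
                    expected += 0.5
            assert d[i[x], i[y]] == pytest.approx(expected)

    def test_symmetry_and_zero_diagonal(self, rng):
        genes = [random_resolved_tree(list("abcdef"), rng) for _ in range(20)]
        recs = count_quartet_topologies(genes, "abcdef")
        results, _ = classify_quartets(recs)
        _, d = nanuq_distance_matrix(results, "abcdef")
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_nexus_block_structure(self):
        res = [QuartetTestResult(("a", "b", "c", "d"), 0.01, 0.5, "treelike",
                                 (("a", "b"), ("c", "d")))]
        labels, d = nanuq_distance_matrix(res, "abcd")
        text = write_nexus_distances(labels, d)
        assert text.startswith("#NEXUS")
        assert "BEGIN DISTANCES;" in text and "TRIANGLE=LOWER" in text
        for t in labels:
            assert t in text

    def test_missing_quartets_warn(self):
        res = [QuartetTestResult(("a", "b", "c", "d"), math.nan, math.nan,
                                 "nodata", None)]
        with pytest.warns(UserWarning, match="unscored"):
            nanuq_distance_matrix(res, "abcde")
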