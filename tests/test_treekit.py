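import itertools

import dendropy
import numpy as np
import pytest

from plastmark import treekit as tk
from plastmark import synthetic as syn
from plastmark.alignment import Alignment


def _splits(tree):
    return tk.bipartitions(tree)


class TestNewickIO:
    def test_parse_basic(self):
        t = tk.parse_newick("((A,B),(C,D));")
        assert tk.leaf_labels(t) == frozenset("ABCD")
        assert len(_splits(tk.unroot(t))) == 1

    def test_round_trip_preserves_splits(self, rng):
        t = syn.simulate_yule_tree(20, 1.0, rng)
        again = tk.parse_newick(tk.write_newick(t))
        assert _splits(again) == _splits(t)

    def test_support_label_attached(self):
        t = tk.parse_newick("((A:1,B:2)90:0.5,C:1);")
        ab = [nd for nd in t if nd.label == "90"]
        assert len(ab) == 1
        assert ab[0].edge.length == 0.5

    def test_malformed_raises(self):
        with pytest.raises(ValueError):
            tk.parse_newick("((A,B,C);")


class TestPruneUnroot:
    def test_prune_to_subset(self):
        t = tk.parse_newick("((A,B),(C,D),E);")
        p = tk.prune_taxa(t, {"A", "B", "C", "D"})
        assert tk.leaf_labels(p) == frozenset("ABCD")
        assert _splits(p) == {frozenset("AB")}

    def test_prune_full_set_is_identity(self):
        t = tk.parse_newick("((A,B),(C,D),E);")
        assert _splits(tk.prune_taxa(t, tk.leaf_labels(t))) == _splits(t)

    def test_prune_sums_branch_lengths(self):
        t = tk.parse_newick("((A:1,(B:1,X:1):1):1,C:1,D:1);")
        p = tk.prune_taxa(t, {"A", "B", "C", "D"})
        b = next(lf for lf in p.leaf_node_iter() if lf.taxon.label == "B")
        assert b.edge.length == pytest.approx(2.0)

    def test_prune_restriction_oracle(self, rng):
        """Splits of the pruned tree = splits of the original restricted
        to the kept labels (trivial restrictions discarded)."""
        for _ in range(20):
            t = syn.simulate_yule_tree(10, 1.0, rng)
            keep = frozenset(f"t{i}" for i in
                             rng.choice(10, size=6, replace=False) + 1)
            expected = set()
            n = len(keep)
            anchor = min(keep)
            for block in _splits(t):
                r = frozenset(block & keep)
                if len(r) < 2 or n - len(r) < 2:
                    continue
                if anchor not in r:
                    r = frozenset(keep - r)
                expected.add(r)
            assert _splits(tk.prune_taxa(t, keep)) == expected

    def test_prune_too_few(self):
        t = tk.parse_newick("((A,B),(C,D),E);")
        with pytest.raises(ValueError):
            tk.prune_taxa(t, {"A", "B"})

    def test_unroot_three_leaves_star(self):
        u = tk.unroot(tk.parse_newick("((A,B),C);"))
        assert _splits(u) == frozenset()

    def test_unroot_idempotent(self):
        t = tk.parse_newick("(((A,B),C),(D,E));")
        once = tk.unroot(t)
        twice = tk.unroot(once)
        assert _splits(once) == _splits(twice) == _splits(t)

    def test_unroot_caterpillar_split_count(self):
        t = tk.parse_newick("((((A,B),C),D),E);")
        assert len(_splits(tk.unroot(t))) == 2


class TestBipartitions:
    def test_star_tree_empty(self):
        assert _splits(tk.parse_newick("(A,B,C,D);")) == frozenset()

    def test_binary_count_closed_form(self, rng):
        for n in (5, 8, 12):
            t = tk.unroot(syn.simulate_yule_tree(n, 1.0, rng))
            assert len(_splits(t)) == n - 3

    def test_enumeration_example(self):
        t = tk.parse_newick("((A,B),(C,D),E);")
        assert _splits(t) == {frozenset("AB"), frozenset("ABE")}


class TestRFDistance:
    T1 = "((A,B),(C,D),E);"

    @pytest.mark.parametrize("other,rf,nrf", [
        ("((A,B),(C,D),E);", 0, 0.0),
        ("((A,C),(B,D),E);", 4, 1.0),
        ("((A,B),(C,E),D);", 2, 0.5),
    ])
    def test_five_leaf_examples(self, other, rf, nrf):
        t1, t2 = tk.parse_newick(self.T1), tk.parse_newick(other)
        assert tk.rf_distance(t1, t2) == rf
        assert tk.normalized_rf(t1, t2) == pytest.approx(nrf)

    def test_leaf_set_mismatch_names_labels(self):
        t1 = tk.parse_newick("((A,B),(C,D),E);")
        t2 = tk.parse_newick("((A,B),(C,D),F);")
        with pytest.raises(ValueError, match="E.*F"):
            tk.rf_distance(t1, t2)

    def test_metric_properties_against_dendropy(self, rng):
        """Symmetry/triangle inequality, cross-checked against dendropy's
        independent RF implementation on random 7-leaf tree triples."""
        from dendropy.calculate import treecompare
        for _ in range(50):
            trees = []
            ns = dendropy.TaxonNamespace()
            for _ in range(3):
                t = syn.simulate_yule_tree(7, 1.0, rng)
                t2 = dendropy.Tree.get(data=tk.write_newick(t),
                                       schema="newick",
                                       taxon_namespace=ns)
                t2.encode_bipartitions()
                trees.append(t2)
            d = {}
            for i, j in itertools.combinations(range(3), 2):
                mine = tk.rf_distance(trees[i], trees[j])
                theirs = treecompare.symmetric_difference(trees[i], trees[j])
                assert mine == theirs
                assert mine == tk.rf_distance(trees[j], trees[i])
                d[(i, j)] = mine
            assert d[(0, 2)] <= d[(0, 1)] + d[(1, 2)]

    def test_star_vs_star_nrf_zero(self):
        s1 = tk.parse_newick("(A,B,C,D);")
        s2 = tk.parse_newick("(A,B,C,D);")
        assert tk.normalized_rf(s1, s2) == 0.0


class TestGeneToTargetNRF:
    def test_identical_subtree_zero(self):
        target = tk.parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        gene = tk.parse_newick("((A,B),((C,D),(E,F)));")
        assert tk.gene_to_target_nrf(gene, target) == 0.0

    def test_one_nni_on_ten_leaves(self, rng):
        target = syn.simulate_yule_tree(10, 1.0, rng)
        gene = syn.perturb_topology_nni(target, 1, rng)
        assert tk.gene_to_target_nrf(gene, target) == pytest.approx(2 / 14)

    def test_label_missing_from_target(self):
        target = tk.parse_newick("((A,B),(C,D),E);")
        gene = tk.parse_newick("((A,B),(C,Z));")
        with pytest.raises(ValueError, match="Z"):
            tk.gene_to_target_nrf(gene, target)

    def test_too_few_shared_leaves(self):
        target = tk.parse_newick("((A,B),(C,D),E);")
        gene = tk.parse_newick("(A,B,C);")
        with pytest.raises(ValueError):
            tk.gene_to_target_nrf(gene, target)


class TestNJ:
    def test_additive_four_taxon(self):
        labels = list("ABCD")
        m = np.array([[0, 2, 7, 7],
                      [2, 0, 7, 7],
                      [7, 7, 0, 2],
                      [7, 7, 2, 0]], float)
        t = tk.nj_tree(labels, m)
        assert _splits(tk.unroot(t)) == {frozenset("AB")}

    def test_three_taxa_closed_form(self):
        # three-point formulas: a=(dAB+dAC-dBC)/2 etc.
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = tk.nj_tree(list("ABC"), m)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in t.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_label_order_invariance(self, rng):
        labels = [f"t{i}" for i in range(6)]
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        t1 = tk.nj_tree(labels, m)
        perm = rng.permutation(6)
        t2 = tk.nj_tree([labels[i] for i in perm], m[np.ix_(perm, perm)])
        assert _splits(tk.unroot(t1)) == _splits(tk.unroot(t2))

    def test_recovers_additive_topologies(self, rng):
        """NJ recovers the generating topology from exact tree distances."""
        for _ in range(20):
            t = syn.simulate_yule_tree(6, 1.0, rng)
            # build the additive (path-length) matrix from the tree itself
            pdm = t.phylogenetic_distance_matrix()
            labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
            taxa = {tx.label: tx for tx in t.taxon_namespace}
            m = np.array([[pdm.patristic_distance(taxa[a], taxa[b])
                           for b in labels] for a in labels])
            rec = tk.nj_tree(labels, m)
            assert _splits(tk.unroot(rec)) == _splits(tk.unroot(t))

    @pytest.mark.parametrize("bad", [
        np.array([[0, 1], [1, 0]], float),                      # too few
        np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], float),     # asymmetric
        np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]]),  # NaN
    ])
    def test_invalid_matrices(self, bad):
        labels = [f"t{i}" for i in range(len(bad))]
        with pytest.raises(ValueError):
            tk.nj_tree(labels, bad)


def test_jc_distance_matrix_closed_form():
    aln = Alignment(["a", "b", "c"],
                    ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAAAT"])
    labels, d = tk.jc_distance_matrix(aln)
    p = 0.1
    expected = -0.75 * np.log(1 - 4 * p / 3)
    assert d[0, 1] == pytest.approx(expected)
    assert d[1, 2] == 0.0
    assert np.allclose(d, d.T)
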