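"""Distance models, neighbor joining, RF distance, supports, discordance."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from araliome.align import Alignment
from araliome.trees import (SaturationError, bootstrap_support,
                            clade_support_table, collapse_low_support,
                            distance_matrix, get_support, is_monophyletic,
                            nj, nontrivial_splits, read_newick, rf_distance,
                            write_newick)


def _aln(rows, kind="nucleotide"):
    return Alignment(kind=kind, rows=rows)


class TestDistances:
    def test_identical_rows_zero_under_all_models(self):
        aln = _aln([("A", "ACGTACGT"), ("B", "ACGTACGT")])
        for model in ("p", "jc69", "k2p"):
            assert distance_matrix(aln, model).values[0, 1] == 0.0

    def test_jc69_closed_form(self):
        # p = 0.3 -> d = -0.75 ln(0.6) = 0.383119...
        seq_a = "A" * 10
        seq_b = "G" * 3 + "A" * 7
        d = distance_matrix(_aln([("A", seq_a), ("B", seq_b)]), "jc69")
        assert d.values[0, 1] == pytest.approx(-0.75 * math.log(0.6),
                                               abs=1e-12)

    def test_k2p_closed_form(self):
        # P = 0.10 transitions, Q = 0.05 transversions over 20 sites
        seq_a = "A" * 20
        seq_b = "G" * 2 + "C" * 1 + "A" * 17
        d = distance_matrix(_aln([("A", seq_a), ("B", seq_b)]), "k2p")
        expected = -0.5 * math.log(1 - 0.2 - 0.05) - 0.25 * math.log(0.9)
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_saturation_flagged_not_raised(self):
        aln = _aln([("A", "ACGT"), ("B", "CATG")])  # p = 1
        d = distance_matrix(aln, "jc69")
        assert d.saturated[0, 1]
        assert math.isnan(d.values[0, 1])
        with pytest.raises(SaturationError):
            aln3 = _aln([("A", "ACGT"), ("B", "CATG"), ("C", "ACGT")])
            nj(distance_matrix(aln3, "jc69"))

    def test_gap_columns_excluded(self):
        aln = _aln([("A", "ACG-AC"), ("B", "ACGTAC")])
        d = distance_matrix(aln, "p")
        assert d.values[0, 1] == 0.0


def _random_binary_tree(labels, rng):
    """Random topology with random branch lengths (independent oracle uses
    dendropy's patristic distances)."""
    newick_nodes = [f"{lab}:{rng.uniform(0.05, 0.5):.6f}" for lab in labels]
    while len(newick_nodes) > 1:
        i, j = sorted(rng.choice(len(newick_nodes), size=2, replace=False))
        b = newick_nodes.pop(j)
        a = newick_nodes.pop(i)
        newick_nodes.append(f"({a},{b}):{rng.uniform(0.05, 0.5):.6f}")
    return dendropy.Tree.get(data=newick_nodes[0] + ";", schema="newick")


def _patristic(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tax[labels[i]],
                                                       tax[labels[j]])
    return d


class TestNJ:
    def test_additive_four_taxon_recovery(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, .2, .3, .3], [.2, 0, .3, .3],
                      [.3, .3, 0, .2], [.3, .3, .2, 0]])
        tree = nj(d, labels)
        assert nontrivial_splits(tree) == {frozenset({"C", "D"})} \
            or nontrivial_splits(tree) == {frozenset({"A", "B"})}
        assert np.allclose(_patristic(tree, labels), d, atol=1e-12)

    def test_three_taxon_star(self):
        d = np.array([[0, .3, .4], [.3, 0, .5], [.4, .5, 0]])
        tree = nj(d, ["A", "B", "C"])
        # three-point equations: la = (dab + dac - dbc)/2, etc.
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.3)

    def test_taxon_order_permutation_isomorphic(self):
        rng = np.random.default_rng(21)
        labels = [f"t{i}" for i in range(8)]
        true = _random_binary_tree(labels, rng)
        d = _patristic(true, labels)
        t1 = nj(d, labels)
        perm = rng.permutation(8)
        t2 = nj(d[np.ix_(perm, perm)], [labels[k] for k in perm])
        assert rf_distance(t1, t2) == 0

    def test_additive_recovery_random_trees(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            labels = [f"t{i}" for i in range(n)]
            true = _random_binary_tree(labels, rng)
            d = _patristic(true, labels)
            est = nj(d, labels)
            assert np.allclose(_patristic(est, labels), d, atol=1e-9)


class TestRF:
    def test_identical_trees_zero(self):
        t = read_newick("((A,B),C,(D,E));")
        assert rf_distance(t, read_newick("((A,B),C,(D,E));")) == 0

    def test_five_taxon_example(self):
        t1 = read_newick("((A,B),C,(D,E));")
        t2 = read_newick("((A,C),B,(D,E));")
        assert rf_distance(t1, t2) == 2

    def test_matches_dendropy_on_random_pairs(self):
        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(15):
            a = _random_binary_tree(labels, rng)
            b = _random_binary_tree(labels, rng)
            mine = rf_distance(read_newick(a.as_string(schema="newick")),
                               read_newick(b.as_string(schema="newick")))
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=a.as_string(schema="newick"),
                                   schema="newick", taxon_namespace=tns)
            db = dendropy.Tree.get(data=b.as_string(schema="newick"),
                                   schema="newick", taxon_namespace=tns)
            da.encode_bipartitions()
            db.encode_bipartitions()
            assert mine == treecompare.symmetric_difference(da, db)

    def test_maximum_on_disjoint_resolved_trees(self):
        t1 = read_newick("(((A,B),C),(D,(E,F)));")
        t2 = read_newick("(((A,F),D),(C,(B,E)));")
        n = 6
        assert rf_distance(t1, t2) <= 2 * (n - 3)

    def test_taxon_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="X"):
            rf_distance(read_newick("((A,B),(C,X));"),
                        read_newick("((A,B),(C,D));"))


class TestMonophyly:
    def test_simple_cases(self):
        t = read_newick("((A,B),(C,D));")
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})

    def test_empty_and_full_sets_rejected(self):
        t = read_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            is_monophyletic(t, set())
        with pytest.raises(ValueError):
            is_monophyletic(t, {"A", "B", "C", "D"})

    def test_against_bipartition_enumeration(self):
        """Agreement with dendropy bipartition encoding on random trees."""
        rng = np.random.default_rng(13)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(10):
            tree = _random_binary_tree(labels, rng)
            mine = read_newick(tree.as_string(schema="newick"))
            tree.encode_bipartitions()
            all_splits = set()
            for bp in tree.bipartition_encoding:
                mask = bp.leafset_bitmask
                tips = frozenset(
                    t.label for t in tree.taxon_namespace
                    if mask & tree.taxon_namespace.taxon_bitmask(t))
                all_splits.add(tips)
                all_splits.add(frozenset(labels) - tips)
            for _ in range(8):
                k = int(rng.integers(1, 7))
                subset = frozenset(rng.choice(labels, size=k, replace=False))
                assert is_monophyletic(mine, subset) == (subset in all_splits)


class TestSupports:
    def test_uniform_signal_full_support(self):
        # every informative column supports AB|CD
        rows = [("A", "AAAAAAAA"), ("B", "AAAAAAAA"),
                ("C", "GGGGGGGG"), ("D", "GGGGGGGG")]
        tree = bootstrap_support(_aln(rows), B=100, model="p", seed=0)
        supports = [get_support(nd) for nd in tree.preorder_internal_node_iter()
                    if nd.label is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_binary(self):
        rows = [("A", "AAGGAATT"), ("B", "AAGGAACT"),
                ("C", "GGGGTATT"), ("D", "GGAGTATT")]
        tree = bootstrap_support(_aln(rows), B=1, model="p", seed=3)
        for nd in tree.preorder_internal_node_iter():
            if nd.label is not None:
                assert get_support(nd) in (0.0, 100.0)

    def test_seed_reproducibility(self, small_sim):
        aln = small_sim.concatenated()
        t1 = bootstrap_support(aln, B=30, model="k2p", seed=5)
        t2 = bootstrap_support(aln, B=30, model="k2p", seed=5)
        assert write_newick(t1) == write_newick(t2)


class TestCollapse:
    def test_boundary_strictness(self):
        t = read_newick("((A,B)49,C,(D,E)50);")
        out = collapse_low_support(t, 50)
        assert frozenset({"A", "B"}) not in nontrivial_splits(out)
        assert frozenset({"D", "E"}) in nontrivial_splits(out)

    def test_all_supported_unchanged(self):
        t = read_newick("((A,B)90,C,(D,E)75);")
        out = collapse_low_support(t, 50)
        assert nontrivial_splits(out) == nontrivial_splits(t)

    def test_never_increases_splits_or_changes_taxa(self):
        t = read_newick("(((A,B)20,C)80,D,(E,F)10);")
        out = collapse_low_support(t, 60)
        assert len(nontrivial_splits(out)) <= len(nontrivial_splits(t))
        assert {lf.taxon.label for lf in out.leaf_node_iter()} == \
            {lf.taxon.label for lf in t.leaf_node_iter()}


class TestDiscordance:
    def test_identical_trees_zero_rf_identical_columns(self):
        trees = {k: read_newick("((A,B)90,C,(D,E)80);")
                 for k in ("cds", "pos12")}
        report = clade_support_table(trees, {"AB": ("A", "B")})
        assert (report.rf.values == 0).all()
        assert bool(report.clade_table.loc["AB", ("cds", "present")])
        assert report.clade_table.loc["AB", ("cds", "support")] == 90.0

    def test_present_absent_pattern(self):
        trees = {"m1": read_newick("((A,B)90,C,(D,E)80);"),
                 "m2": read_newick("((A,C)70,B,(D,E)80);")}
        report = clade_support_table(trees, {"AB": ("A", "B"),
                                             "DE": ("D", "E")})
        row = report.clade_table.loc["AB"]
        assert bool(row[("m1", "present")]) and not bool(row[("m2", "present")])
        assert report.best_matrix["AB"] == "m1"
        assert report.rf.loc["m1", "m2"] == 2
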