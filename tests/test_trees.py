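"""Tree structure, Newick round-trips, splits, and topology operations."""

import itertools

import dendropy
import numpy as np
import pytest

import blowphylo as bp
from blowphylo.trees import (
    NewickParseError,
    TreeError,
    nni_neighbors,
    reroot_at_tip_neighbor,
    splits_table,
    unroot,
)
from conftest import random_branched_tree


class TestParsing:
    def test_two_tip_tree_is_unrooted_with_no_internal_branches(self):
        t = bp.parse_newick("(A,B);")
        assert sorted(t.tip_labels()) == ["A", "B"]
        assert not t.rooted
        assert bp.splits(t) == set()

    def test_branch_lengths_and_path_sums(self):
        t = bp.parse_newick("((A:1.0,B:1.0):0.5,C:1.0);")
        assert len(t) == 3
        assert bp.patristic_distance(t, "A", "C") == pytest.approx(2.5)

    def test_missing_semicolon_reports_offset(self):
        with pytest.raises(NewickParseError, match="offset"):
            bp.parse_newick("(A,B)")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            bp.parse_newick("(A,(A,B));")

    def test_quoted_labels_and_comments(self):
        t = bp.parse_newick("('taxon one'[a comment]:1.0,B:2.0,C:1.5);")
        assert "taxon one" in t.taxon_set()

    def test_numeric_internal_labels_become_support(self):
        t = bp.parse_newick("((A:1,B:1)95:0.5,C:1,D:1);")
        internal = [n for n in t.postorder() if not n.is_tip and n.parent]
        assert internal[0].support == 95.0

    @pytest.mark.parametrize("seed", range(5))
    def test_write_parse_roundtrip_preserves_splits(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(20)]
        t = random_branched_tree(taxa, rng)
        back = bp.parse_newick(bp.write_newick(t))
        assert bp.rf_distance(t, back) == 0
        for a, b in [("t0", "t7"), ("t3", "t19")]:
            assert bp.patristic_distance(t, a, b) == pytest.approx(
                bp.patristic_distance(back, a, b)
            )


class TestRfDistance:
    def test_identity_and_textbook_pair(self):
        t1 = bp.parse_newick("((A,B),(C,D));")
        t2 = bp.parse_newick("((A,C),(B,D));")
        assert bp.rf_distance(t1, t1) == 0
        assert bp.rf_distance(t1, t2) == 2

    def test_tip_set_mismatch_raises(self):
        with pytest.raises(TreeError):
            bp.rf_distance(bp.parse_newick("(A,B,C);"), bp.parse_newick("(A,B,D);"))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_split_symmetric_difference_and_dendropy(self, seed):
        rng = np.random.default_rng(100 + seed)
        taxa = [f"t{i}" for i in range(10)]
        a, b = (random_branched_tree(taxa, rng) for _ in range(2))
        expected = len(bp.splits(a) ^ bp.splits(b))
        assert bp.rf_distance(a, b) == expected
        tns = dendropy.TaxonNamespace()
        da = dendropy.Tree.get(data=bp.write_newick(a), schema="newick",
                               taxon_namespace=tns)
        db = dendropy.Tree.get(data=bp.write_newick(b), schema="newick",
                               taxon_namespace=tns)
        assert bp.rf_distance(a, b) == int(
            dendropy.calculate.treecompare.symmetric_difference(da, db)
        )

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(7)
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(10):
            x, y, z = (random_branched_tree(taxa, rng) for _ in range(3))
            assert bp.rf_distance(x, y) == bp.rf_distance(y, x)
            assert bp.rf_distance(x, z) <= bp.rf_distance(x, y) + bp.rf_distance(y, z)


class TestRestriction:
    def test_cherry_kept_adjacent(self):
        t = bp.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        sub = bp.restrict_to_taxa(t, {"A", "B", "C"})
        assert sub.taxon_set() == {"A", "B", "C"}
        # suppressed node lengths are summed
        assert bp.patristic_distance(sub, "A", "C") == pytest.approx(4.0)

    def test_keep_all_is_identity(self):
        t = bp.parse_newick("((A,B),(C,D),E);")
        assert bp.rf_distance(bp.restrict_to_taxa(t, t.taxon_set()), t) == 0

    def test_unknown_label_listed(self):
        t = bp.parse_newick("(A,B,C);")
        with pytest.raises(TreeError, match="Z"):
            bp.restrict_to_taxa(t, {"A", "Z"})

    @pytest.mark.parametrize("keep_n", [4, 5, 6])
    def test_induced_splits_match_restricted_split_sets(self, keep_n):
        # caterpillar tree; oracle restricts every split directly
        newick = "(t0,(t1,(t2,(t3,(t4,(t5,(t6,t7)))))));"
        t = bp.parse_newick(newick)
        keep = {f"t{i}" for i in range(keep_n)}
        sub = bp.restrict_to_taxa(t, keep)
        anchor = min(keep)
        expected = set()
        for s in bp.splits(t):
            side = s & keep
            side = keep - side if anchor in side else side
            if 2 <= len(side) <= len(keep) - 2:
                expected.add(frozenset(side))
        assert bp.splits(sub) == expected

    def test_commutes_with_relabeling(self):
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(8)]
        t = random_branched_tree(taxa, rng)
        mapping = {lab: f"x{lab}" for lab in taxa}
        relabeled = t.copy()
        for n in relabeled.postorder():
            if n.is_tip:
                n.label = mapping[n.label]
        keep = {"t0", "t2", "t4", "t6"}
        a = bp.restrict_to_taxa(t, keep)
        for n in a.postorder():
            if n.is_tip:
                n.label = mapping[n.label]
        b = bp.restrict_to_taxa(relabeled, {mapping[k] for k in keep})
        assert bp.rf_distance(a, b) == 0


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105)])
    def test_double_factorial_counts(self, n, count):
        trees = bp.enumerate_unrooted_topologies([f"t{i}" for i in range(n)])
        assert len(trees) == count

    def test_all_pairwise_distinct_at_n6(self):
        trees = bp.enumerate_unrooted_topologies([f"t{i}" for i in range(6)])
        keys = {frozenset(bp.splits(t)) for t in trees}
        assert len(keys) == 105

    @pytest.mark.parametrize("n", [3, 10])
    def test_out_of_range_guard(self, n):
        with pytest.raises(TreeError):
            bp.enumerate_unrooted_topologies([f"t{i}" for i in range(n)])


class TestConstraints:
    def test_backbone_hypotheses_vs_chrysomyinae_group3_clade(self):
        con = bp.CladeConstraint(
            ["Chrysomyinae", "Luciliinae", "Calliphorinae", "Toxotarsinae"]
        )
        assert bp.satisfies_constraints(bp.backbone_fixture("T2").tree, [con])
        assert not bp.satisfies_constraints(bp.backbone_fixture("T1").tree, [con])

    def test_full_tip_set_always_satisfied(self):
        t = bp.parse_newick("((A,B),(C,D),E);")
        assert bp.satisfies_constraints(t, [bp.CladeConstraint(t.taxon_set())])

    def test_group1_monophyly_only_under_t1(self):
        con = bp.CladeConstraint(["Chrysomyinae", "Phumosiinae"])
        results = {
            h: bp.satisfies_constraints(bp.backbone_fixture(h).tree, [con])
            for h in ("T1", "T2", "T3")
        }
        assert results == {"T1": True, "T2": False, "T3": False}

    def test_t3_places_chrysomyinae_with_rhiniids(self):
        con = bp.CladeConstraint(["Chrysomyinae", "Rhiniidae", "Bengaliinae"])
        assert bp.satisfies_constraints(bp.backbone_fixture("T3").tree, [con])


class TestManipulation:
    def test_reroot_preserves_topology_and_paths(self):
        rng = np.random.default_rng(11)
        t = random_branched_tree([f"t{i}" for i in range(9)], rng)
        r = reroot_at_tip_neighbor(t, "t5")
        assert bp.rf_distance(t, r) == 0
        assert bp.patristic_distance(t, "t0", "t8") == pytest.approx(
            bp.patristic_distance(r, "t0", "t8")
        )

    def test_nni_neighbors_are_distinct_distance_two(self):
        t = bp.parse_newick("((A,B),(C,D),E);")
        nbrs = nni_neighbors(t)
        assert len(nbrs) == 2 * len(bp.splits(t))
        for nb in nbrs:
            assert bp.rf_distance(t, nb) == 2

    def test_unroot_collapses_bifurcating_root(self):
        t = bp.parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        u = unroot(t)
        assert len(u.root.children) == 3
        assert bp.patristic_distance(u, "A", "C") == pytest.approx(3.0)

    def test_splits_table_lists_nontrivial_bipartitions(self):
        t = bp.parse_newick("((A,B),(C,D),E);")
        rows = splits_table(t)
        assert len(rows) == len(bp.splits(t))
        for side, other in rows:
            assert set(side.split("|")).isdisjoint(other.split("|"))
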