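"""ΔpL tables, FcLM mechanics, RELL resampling, KH/SH/AU behavior.

Heavy simulation-based checks at the full study scale live in
test_acceptance.py; here the mechanics are verified on small matrices.
"""

import numpy as np
import pytest

import blowphylo as bp
from blowphylo.likelihood import SiteLogLikMatrix, site_loglik_matrix
from blowphylo.topotests import FcLMResult, rell_resample
from blowphylo.trees import nni_neighbors


@pytest.fixture(scope="module")
def small_sim():
    """A 20-gene JC supermatrix on the T1 backbone, plus the hypotheses."""
    model = bp.jc(gamma_shape=1.0)
    fixture = bp.backbone_fixture("T1")
    specs = [bp.GeneSpec(f"g{i:02d}", 60) for i in range(20)]
    aln, parts = bp.simulate_supermatrix(fixture.tree, specs, model, 77)
    trees = {h: bp.backbone_fixture(h).tree for h in ("T1", "T2", "T3")}
    return model, fixture, aln, parts, trees


class TestDeltaPl:
    def test_identical_trees_give_zero_deltas(self, small_sim):
        model, fixture, aln, parts, _ = small_sim
        table = bp.per_partition_delta_pl(
            aln, parts, {"a": fixture.tree, "b": fixture.tree}, model,
            optimize=False,
        )
        assert np.allclose(table.delta(("a", "b")), 0.0)
        assert bp.count_favoring(table, ("a", "b")) == (0, 0, 20)

    def test_single_gene_delta_equals_total_difference(self, small_sim):
        model, fixture, aln, parts, trees = small_sim
        gene = parts[0]
        sub = aln.subset_sites(np.arange(gene.start, gene.end))
        single = bp.PartitionMap([bp.Partition(gene.name, 0, gene.length)])
        table = bp.per_partition_delta_pl(
            sub, single, {"T1": trees["T1"], "T2": trees["T2"]}, model,
            optimize=False,
        )
        la, _ = bp.tree_loglik(trees["T1"], sub, model)
        lb, _ = bp.tree_loglik(trees["T2"], sub, model)
        assert table.delta(("T1", "T2"))[0] == pytest.approx(la - lb, abs=1e-9)

    def test_delta_additivity_matches_totals(self, small_sim):
        model, _, aln, parts, trees = small_sim
        table = bp.per_partition_delta_pl(aln, parts, trees, model, optimize=False)
        for pair in table.pairs:
            a, b = pair
            assert table.delta(pair).sum() == pytest.approx(
                table.totals[a] - table.totals[b], abs=1e-6
            )

    def test_count_favoring_signs_and_ties(self):
        import pandas as pd
        from blowphylo.topotests import DeltaPLTable

        df = pd.DataFrame({"gene": list("abc"), "delta_x_y": [1.0, -2.0, 0.5]})
        table = DeltaPLTable(df, ["x", "y"], [("x", "y")], {})
        assert bp.count_favoring(table, ("x", "y")) == (2, 1, 0)

    def test_empty_partition_map_rejected(self, small_sim):
        model, _, aln, _, trees = small_sim
        with pytest.raises(ValueError):
            bp.per_partition_delta_pl(
                aln, bp.PartitionMap([]), trees, model
            )


class TestFclm:
    def test_singleton_groups_give_one_quartet(self, small_sim):
        model, fixture, aln, _, _ = small_sim
        res = bp.fclm(
            aln,
            {
                "a": ("Chrysomyinae",),
                "b": ("Ameniinae",),
                "c": ("Luciliinae",),
                "d": ("Outgroup",),
            },
            model,
            seed=1,
        )
        assert res.n_quartets == 1
        assert res.weights.shape == (1, 3)

    def test_weights_on_simplex_and_percentages_sum_to_100(self, small_sim):
        model, fixture, aln, _, _ = small_sim
        g = fixture.groups
        res = bp.fclm(
            aln,
            {
                "group1": g["group1"],
                "group2a": g["group2a"],
                "group3": g["group3"],
                "outgroup": g["outgroup"],
            },
            model,
            seed=2,
        )
        assert np.allclose(res.weights.sum(axis=1), 1.0)
        assert (res.weights >= 0).all()
        assert sum(res.basin_percent().values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(res.basin_counts().values()) + res.n_dropped == 2 * 3 * 3 * 1
        assert sum(res.region7_counts().values()) == res.n_quartets

    def test_overlapping_groups_rejected(self, small_sim):
        model, _, aln, _, _ = small_sim
        with pytest.raises(ValueError):
            bp.fclm(
                aln,
                [("Chrysomyinae",), ("Chrysomyinae",), ("Luciliinae",), ("Outgroup",)],
                model,
            )

    def test_sparse_quartet_dropped(self, small_sim):
        model, fixture, aln, _, _ = small_sim
        # blank out one taxon entirely: every quartet using it lacks sites
        codes = aln.codes.copy()
        idx = aln.labels.index("Chrysomyinae")
        codes[idx, :] = aln.alphabet.code_of["N"]
        blanked = bp.Alignment(aln.labels, codes, aln.alphabet)
        res = bp.fclm(
            blanked,
            [("Chrysomyinae",), ("Ameniinae",), ("Luciliinae",), ("Outgroup",)],
            model,
            seed=3,
        )
        assert res.n_dropped == 1 and res.n_quartets == 0

    def test_region7_geometry(self):
        res = FcLMResult(
            ("a", "b", "c", "d"),
            [("w", "x", "y", "z")] * 4,
            np.array(
                [
                    [0.8, 0.15, 0.05],   # corner 0
                    [0.5, 0.45, 0.05],   # edge between 0 and 1
                    [0.4, 0.35, 0.25],   # center
                    [0.1, 0.2, 0.7],     # corner 2
                ]
            ),
            0,
            0,
        )
        assert list(res.regions7) == [0, 3, 6, 2]

    def test_variants_under_t1_both_favor_group1_basal(self):
        """Small-scale version of the paraphyly-aware mapping."""
        model = bp.jc(gamma_shape=1.0)
        fixture = bp.backbone_fixture("T1")
        specs = [bp.GeneSpec("g1", 2000)]
        aln, _ = bp.simulate_supermatrix(fixture.tree, specs, model, 55)
        g = fixture.groups
        wo2b, wo2a = bp.fclm_paraphyly_variants(
            aln, g["group1"], g["group2a"], g["group2b"], g["group3"],
            model, seed=5,
        )
        for res in (wo2b, wo2a):
            pct = res.basin_percent()
            basal = next(v for k, v in pct.items() if "group1+outgroup" in k)
            assert basal == max(pct.values())
            assert basal >= 70.0


class TestRell:
    def test_constant_sites_give_constant_totals(self):
        sll = SiteLogLikMatrix(["t"], np.full((1, 50), -2.0))
        rep = rell_resample(sll, 1.0, 200, 1)
        assert np.allclose(rep, 50 * -2.0)

    def test_replicate_mean_tracks_scaled_total(self):
        rng = np.random.default_rng(3)
        vals = -rng.exponential(1.0, size=(2, 400))
        sll = SiteLogLikMatrix(["a", "b"], vals)
        for scale in (0.5, 1.0, 1.4):
            rep = rell_resample(sll, scale, 5000, 7)
            m_rep = int(round(scale * 400))
            expected = vals.sum(axis=1) * m_rep / 400
            sd = vals.std(axis=1) * np.sqrt(m_rep)
            for t in range(2):
                assert abs(rep[t].mean() - expected[t]) < 3 * sd[t] / np.sqrt(5000)

    def test_seed_reproducibility_and_empty_guard(self):
        sll = SiteLogLikMatrix(["a"], np.zeros((1, 10)) - 1.0)
        assert np.array_equal(
            rell_resample(sll, 1.0, 50, 9), rell_resample(sll, 1.0, 50, 9)
        )
        with pytest.raises(ValueError):
            rell_resample(SiteLogLikMatrix(["a"], np.empty((1, 0))), 1.0, 10, 0)


class TestTopologyTestSuite:
    def test_identical_rows_tie_case(self):
        rng = np.random.default_rng(8)
        row = -rng.exponential(1.0, 300)
        sll = SiteLogLikMatrix(["a", "b"], np.vstack([row, row]))
        rep = bp.topology_test_suite(sll, replicates=400, seed=1)
        tbl = rep.table.set_index("tree")
        assert tbl.loc["a", "p_KH"] == 1.0 and tbl.loc["b", "p_KH"] == 1.0
        assert tbl.loc["a", "p_SH"] == 1.0 and tbl.loc["b", "p_SH"] == 1.0
        assert abs(tbl.loc["a", "p_AU"] - 0.5) < 0.1
        assert "tie-with-best" in tbl.loc["b", "flags"]

    def test_strong_signal_rejects_wrong_trees(self):
        model = bp.jc()
        true = bp.parse_newick(
            "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,(E:0.2,F:0.2):0.1);"
        )
        aln = bp.simulate_alignment(true, model, 2000, 21)
        cands = {"true": true}
        nbrs = nni_neighbors(true)
        cands["alt1"], cands["alt2"] = nbrs[0], nbrs[1]
        fitted = {k: bp.optimize_branch_lengths(t, aln, model) for k, t in cands.items()}
        sll = site_loglik_matrix(fitted, aln, model)
        rep = bp.topology_test_suite(sll, replicates=500, seed=2)
        tbl = rep.table.set_index("tree")
        assert tbl.loc["true", "delta"] == 0.0
        assert tbl.loc["true", "p_AU"] > 0.05
        assert tbl.loc["alt1", "p_AU"] < 0.05
        assert tbl.loc["alt2", "p_AU"] < 0.05
        assert (tbl["p_KH"] <= 1).all() and (tbl["p_SH"] >= tbl["p_KH"] - 1e-9).all()

    def test_single_tree_rejected(self):
        sll = SiteLogLikMatrix(["a"], np.zeros((1, 10)))
        with pytest.raises(ValueError):
            bp.topology_test_suite(sll)
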