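import numpy as np
import pandas as pd
import pytest
import dendropy
from hypothesis import given, strategies as st

from rhizoasm.io import OtuTable
from rhizoasm.assembly import (
    beta_mntd,
    beta_mntd_matrix,
    bnti_matrix,
    rc_bray_matrix,
    classify_pair,
    pair_assembly,
    process_fractions,
    pnst,
    PROCESSES,
)
from rhizoasm.trees import patristic_matrix
from rhizoasm.simulate import simulate_tree


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


class TestBetaMntd:
    def test_identical_communities_zero(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        t = OtuTable.from_arrays([[5, 5], [3, 3], [1, 1]], ["A", "B", "C"], ["x", "y"])
        assert beta_mntd(t, tree, ("x", "y")) == pytest.approx(0.0)

    def test_hand_computed_two_singletons(self):
        # patristic A-C distance = 1 + 1 + 2 = 4; each direction contributes 4
        tree = _tree("((A:1,B:1):1,C:2);")
        t = OtuTable.from_arrays([[7, 0], [0, 0], [0, 3]], ["A", "B", "C"], ["x", "y"])
        assert beta_mntd(t, tree, ("x", "y")) == pytest.approx(4.0)

    def test_unweighted_equals_weighted_for_even_abundances(self):
        tree = simulate_tree(8, seed=1)
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
        counts = np.zeros((8, 2), dtype=int)
        counts[:4, 0] = 5
        counts[4:, 1] = 5
        t = OtuTable.from_arrays(counts, taxa, ["x", "y"])
        w = beta_mntd(t, tree, ("x", "y"), weighted=True)
        u = beta_mntd(t, tree, ("x", "y"), weighted=False)
        assert w == pytest.approx(u)

    def test_taxon_absent_from_tree(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        t = OtuTable.from_arrays([[1, 1]], ["ghost"], ["x", "y"])
        with pytest.raises(ValueError, match="ghost"):
            beta_mntd(t, tree, ("x", "y"))


class TestBnti:
    def test_identical_pair_flagged_nan(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        t = OtuTable.from_arrays([[5, 5], [3, 3], [1, 1]], ["A", "B", "C"], ["x", "y"])
        with pytest.warns(UserWarning, match="zero null spread"):
            z, _ = bnti_matrix(t, tree, n_null=99, seed=0)
        assert np.isnan(z.loc["x", "y"])

    def test_invariant_to_branch_length_scaling(self):
        tree_a = simulate_tree(20, seed=3)
        tree_b = tree_a.clone(depth=1)
        for e in tree_b.preorder_edge_iter():
            if e.length is not None:
                e.length *= 7.5
        taxa = [lf.taxon.label for lf in tree_a.leaf_node_iter()]
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(20, 4))
        counts[0] += 1
        t = OtuTable.from_arrays(counts, taxa, list("wxyz"))
        za, _ = bnti_matrix(t, tree_a, n_null=199, seed=5)
        zb, _ = bnti_matrix(t, tree_b, n_null=199, seed=5)
        np.testing.assert_allclose(za.to_numpy(), zb.to_numpy(), atol=1e-9)

    def test_n_null_floor(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        t = OtuTable.from_arrays([[5, 1], [3, 2], [1, 9]], ["A", "B", "C"], ["x", "y"])
        with pytest.raises(ValueError, match="99"):
            bnti_matrix(t, tree, n_null=10)


class TestRcBray:
    def test_identical_samples_minus_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 30, size=12)
        counts = np.column_stack([col, col] + [rng.integers(0, 30, size=12)
                                               for _ in range(3)])
        t = OtuTable.from_arrays(counts, [f"t{i}" for i in range(12)],
                                 [f"s{j}" for j in range(5)])
        rc = rc_bray_matrix(t, n_null=99, seed=2)
        assert rc.loc["s0", "s1"] == pytest.approx(-1.0)

    def test_bounds(self, random_table):
        rc = rc_bray_matrix(random_table, n_null=99, seed=3)
        vals = rc.to_numpy()
        assert (vals >= -1 - 1e-12).all() and (vals <= 1 + 1e-12).all()
        np.testing.assert_allclose(vals, vals.T, atol=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "bnti_value,rc,expected",
        [
            (-2.5, 0.1, "homogeneous_selection"),
            (2.5, 0.1, "variable_selection"),
            (1.0, 0.97, "dispersal_limitation"),
            (1.0, -0.97, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated_drift"),
            (2.0, 0.99, "dispersal_limitation"),   # boundary: not selection
            (-2.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.95, "undominated_drift"),      # boundary: not dispersal
        ],
    )
    def test_threshold_rules(self, bnti_value, rc, expected):
        assert classify_pair(bnti_value, rc) == expected

    def test_nan_bnti_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(float("nan"), 0.0)

    @given(st.floats(-5, 5), st.floats(-1, 1))
    def test_totality(self, b, r):
        assert classify_pair(b, r) in PROCESSES


class TestFractions:
    def _pairs(self, processes):
        return pd.DataFrame(
            {"sample_a": [f"a{i}" for i in range(len(processes))],
             "sample_b": [f"b{i}" for i in range(len(processes))],
             "bmntd": 0.0, "bnti": 0.0, "rc_bray": 0.0, "process": processes}
        )

    def test_single_process_hundred_percent(self):
        fr = process_fractions(self._pairs(["dispersal_limitation"] * 4))
        assert fr.loc["all", "dispersal_limitation"] == pytest.approx(100.0)

    def test_even_split(self):
        fr = process_fractions(
            self._pairs(["dispersal_limitation"] * 2 + ["undominated_drift"] * 2)
        )
        assert fr.loc["all", "dispersal_limitation"] == pytest.approx(50.0)
        assert fr.loc["all", "undominated_drift"] == pytest.approx(50.0)

    def test_grouping_keeps_within_group_pairs(self):
        pairs = pd.DataFrame(
            {"sample_a": ["s1", "s1", "s3"], "sample_b": ["s2", "s3", "s4"],
             "bmntd": 0.0, "bnti": 0.0, "rc_bray": 0.0,
             "process": ["undominated_drift"] * 3}
        )
        grouping = pd.Series({"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"})
        fr = process_fractions(pairs, grouping)
        assert fr.loc["g1", "n_pairs"] == 1
        assert fr.loc["g2", "n_pairs"] == 1
        np.testing.assert_allclose(fr[list(PROCESSES)].sum(axis=1), 100.0)


class TestPnst:
    def test_bounds_on_random_table(self, random_table):
        tree = simulate_tree(50, seed=9)
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
        table = OtuTable.from_arrays(random_table.counts, taxa,
                                     random_table.sample_ids)
        grouping = pd.Series(
            {s: ("g1" if i < 5 else "g2") for i, s in enumerate(table.sample_ids)}
        )
        results = pnst(table, tree, grouping, n_null=99, seed=4)
        for r in results:
            assert 0.0 <= r.pnst <= 1.0
            assert r.verdict == ("stochastic" if r.pnst > 0.5 else "deterministic")

    def test_small_group_error(self, random_table):
        tree = simulate_tree(50, seed=9)
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
        table = OtuTable.from_arrays(random_table.counts, taxa,
                                     random_table.sample_ids)
        grouping = pd.Series(
            {s: ("tiny" if i < 2 else "rest") for i, s in enumerate(table.sample_ids)}
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            pnst(table, tree, grouping, n_null=99, seed=4)


class TestPnstScenarioContrast:
    def test_strong_selection_lowers_pnst_vs_paired_neutral(self):
        """Strong habitat filtering with distinct optima per regime pulls
        pNST down relative to seed-matched neutral assembly in every
        replicate, with a substantial share of groups crossing the 0.5
        deterministic boundary."""
        from rhizoasm.simulate import distinct_env_by_regime, scenario_preset, emit_study

        below_boundary, n_groups = 0, 0
        for seed in range(5):
            sel = emit_study(scenario_preset(
                "selection", seed=900 + seed, selection_strength=100.0,
                community_size=200, trait_eb_decay=8.0,
                env_by_cell=distinct_env_by_regime(spread=2.0)))
            neu = emit_study(scenario_preset("neutral", seed=900 + seed))
            vals = {}
            for name, study in (("selection", sel), ("neutral", neu)):
                groups = study.metadata.set_index("sample_id")["regime"]
                res = pnst(study.table, study.tree, groups, n_null=99,
                           seed=910 + seed)
                vals[name] = [r.pnst for r in res]
            assert np.mean(vals["selection"]) < np.mean(vals["neutral"])
            below_boundary += sum(v < 0.5 for v in vals["selection"])
            n_groups += len(vals["selection"])
        assert below_boundary / n_groups >= 0.25


class TestPairAssemblyIntegration:
    def test_tidy_output_and_exclusions(self, small_neutral_study):
        study = small_neutral_study
        sub = OtuTable(study.table.data.iloc[:, :12])
        pairs = pair_assembly(sub, study.tree, n_null=99, seed=6)
        assert set(pairs.columns) == {"sample_a", "sample_b", "bmntd", "bnti",
                                      "rc_bray", "process"}
        assert len(pairs) + pairs.attrs["n_excluded"] == 12 * 11 // 2
        assert set(pairs["process"]) <= set(PROCESSES)
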