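import numpy as np
import pandas as pd
import pytest
import networkx as nx
from scipy import stats as sps

from rhizoasm.io import OtuTable
from rhizoasm.network import (
    spearman_matrix,
    threshold_network,
    rmt_scan,
    topology_metrics,
    module_detect,
    zi_pi,
    random_baseline,
    rewired_replicates,
    CooccurrenceNetwork,
)


def _net_from_graph(g: nx.Graph) -> CooccurrenceNetwork:
    for _, _, d in g.edges(data=True):
        d.setdefault("rho", 1.0)
        d.setdefault("sign", "+")
    return CooccurrenceNetwork(graph=g)


class TestSpearman:
    def test_monotone_pairs(self):
        counts = np.array([[1, 2, 3, 4, 5, 6],
                           [2, 4, 9, 16, 25, 36],
                           [60, 50, 40, 30, 20, 10]])
        t = OtuTable.from_arrays(counts, ["a", "b", "c"], [f"s{i}" for i in range(6)])
        rho, p = spearman_matrix(t)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_tied_data_average_rank_oracle(self):
        """rho on tied data equals the Pearson correlation of average
        ranks, computed by hand."""
        x = np.array([1, 1, 2, 3, 3, 4])
        y = np.array([2, 3, 3, 5, 4, 6])
        t = OtuTable.from_arrays(np.vstack([x, y]), ["a", "b"],
                                 [f"s{i}" for i in range(6)])
        rho, _ = spearman_matrix(t)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_constant_taxon_excluded_with_warning(self):
        counts = np.array([[5, 5, 5, 5], [1, 2, 3, 4], [4, 3, 2, 1]])
        t = OtuTable.from_arrays(counts, ["const", "up", "down"],
                                 [f"s{i}" for i in range(4)])
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_matrix(t)
        assert "const" not in rho.index

    def test_prevalence_filter_and_min_samples(self):
        counts = np.array([[1, 0, 0, 0], [1, 2, 3, 4], [4, 3, 2, 1]])
        t = OtuTable.from_arrays(counts, ["rare", "up", "down"],
                                 [f"s{i}" for i in range(4)])
        rho, _ = spearman_matrix(t, prevalence_min=0.5)
        assert "rare" not in rho.index
        t2 = OtuTable.from_arrays(counts[:, :3], ["a", "b", "c"], ["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(t2)


class TestThreshold:
    def _corr(self):
        taxa = ["a", "b", "c"]
        rho = pd.DataFrame(
            [[1.0, 0.9, -0.9], [0.9, 1.0, 0.5], [-0.9, 0.5, 1.0]],
            index=taxa, columns=taxa,
        )
        p = pd.DataFrame(0.001, index=taxa, columns=taxa)
        return rho, p

    def test_bacterial_cutoff_keeps_strong_edges(self):
        rho, p = self._corr()
        net = threshold_network(rho, p, dialect="fixed_cutoff", cutoff=0.88)
        edges = {(a, b): s for a, b, _, s in net.edges}
        assert ("a", "b") in edges and edges[("a", "b")] == "+"
        assert ("a", "c") in edges and edges[("a", "c")] == "-"
        assert ("b", "c") not in edges  # rho = 0.5 dropped

    def test_rho_p_dialect_needs_both(self):
        rho, p = self._corr()
        p.loc["a", "b"] = p.loc["b", "a"] = 0.5
        net = threshold_network(rho, p, dialect="rho_p", cutoff=0.6, p_max=0.01)
        edges = {(a, b) for a, b, _, _ in net.edges}
        assert edges == {("a", "c")}

    def test_empty_network_warns(self):
        rho, p = self._corr()
        with pytest.warns(UserWarning, match="no edges"):
            net = threshold_network(rho, p, cutoff=0.99)
        assert net.graph.number_of_edges() == 0

    def test_cutoff_validation(self):
        rho, p = self._corr()
        with pytest.raises(ValueError):
            threshold_network(rho, p, cutoff=1.5)
        with pytest.raises(ValueError, match="dialect"):
            threshold_network(rho, p, dialect="magic")


class TestTopology:
    def test_complete_graph_k4(self):
        net = _net_from_graph(nx.complete_graph(4))
        topo = topology_metrics(net)
        assert topo.avgK == pytest.approx(3.0)
        assert topo.avgCC == pytest.approx(1.0)
        assert topo.GD == pytest.approx(1.0)
        assert topo.HD == pytest.approx(1.0)
        assert topo.positive_pct + topo.negative_pct == pytest.approx(100.0)

    def test_path_graph_clustering_zero(self):
        topo = topology_metrics(_net_from_graph(nx.path_graph(3)))
        assert topo.avgCC == 0.0

    def test_two_triangles_modularity_half(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        net = _net_from_graph(g)
        modules = module_detect(net)
        assert len(set(modules.values())) == 2
        topo = topology_metrics(net)
        assert topo.modularity == pytest.approx(0.5)

    def test_hd_le_gd_on_connected_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = nx.gnm_random_graph(12, 25, seed=int(rng.integers(1e6)))
            if not nx.is_connected(g):
                continue
            topo = topology_metrics(_net_from_graph(g))
            assert topo.HD <= topo.GD + 1e-12

    def test_single_edge_degenerate(self):
        net = _net_from_graph(nx.Graph([(0, 1)]))
        topo = topology_metrics(net)
        assert topo.n_links == 1
        assert np.isnan(topo.powerlaw_r2)  # single degree value, no fit


class TestModules:
    def test_planted_partition_recovery(self):
        """Greedy modularity recovers a strong planted partition (adjusted
        Rand > 0.9 on average over seeds)."""
        from sklearn.metrics import adjusted_rand_score

        scores = []
        for seed in range(20):
            g = nx.planted_partition_graph(4, 15, 0.9, 0.05, seed=seed)
            truth = [g.nodes[n]["block"] for n in g.nodes]
            net = _net_from_graph(nx.Graph(g))
            modules = module_detect(net)
            scores.append(adjusted_rand_score(truth, [modules[n] for n in g.nodes]))
        assert np.mean(scores) > 0.9

    def test_deterministic_and_sorted_by_size(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (6, 7)])
        m1 = module_detect(_net_from_graph(g.copy()))
        m2 = module_detect(_net_from_graph(g.copy()))
        assert m1 == m2
        assert m1[6] == m1[7] == 2  # smallest module gets the last id


class TestZiPi:
    def test_within_module_only_node_pi_zero(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        net = _net_from_graph(g)
        stats = zi_pi(net, module_detect(net))
        assert (stats["Pi"] == 0).all()
        assert (stats["role"] == "peripheral").all()

    def test_hand_computed_seven_node_fixture(self):
        """Hub node 0 sits in module {0,1,2,3} and reaches across to module
        {4,5,6}: Zi and Pi follow from the hand-counted degree split."""
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 2), (0, 4), (4, 5), (4, 6), (5, 6)])
        modules = {0: 0, 1: 0, 2: 0, 3: 0, 4: 1, 5: 1, 6: 1}
        stats = zi_pi(_net_from_graph(g), modules)
        # within-module degrees in module 0: node0=3, node1=2, node2=2, node3=1
        mean, sd = np.mean([3, 2, 2, 1]), np.std([3, 2, 2, 1])
        assert stats.loc[0, "Zi"] == pytest.approx((3 - mean) / sd)
        # node 0 degree 4: 3 within, 1 to module 1
        assert stats.loc[0, "Pi"] == pytest.approx(1 - (3 / 4) ** 2 - (1 / 4) ** 2)
        # node 4: degree 3, one link into module 0
        assert stats.loc[4, "Pi"] == pytest.approx(1 - (2 / 3) ** 2 - (1 / 3) ** 2)

    def test_role_thresholds_and_keystone_rule(self):
        # star inside module 0 forces a high within-module z-score
        g = nx.star_graph(12)
        g.add_edge(1, 2)
        modules = {n: 0 for n in g.nodes}
        stats = zi_pi(_net_from_graph(g), modules)
        assert stats.loc[0, "Zi"] >= 2.5
        assert stats.loc[0, "role"] == "module_hub"
        assert bool(stats.loc[0, "keystone"])
        assert not bool(stats.loc[3, "keystone"])

    def test_sd_zero_convention(self):
        g = nx.Graph([(0, 1), (2, 3)])
        modules = {0: 0, 1: 0, 2: 1, 3: 1}
        stats = zi_pi(_net_from_graph(g), modules)
        assert (stats["Zi"] == 0).all()


class TestRandomBaseline:
    def test_degree_multiset_preserved(self):
        g = nx.planted_partition_graph(3, 8, 0.8, 0.1, seed=1)
        g = nx.Graph(g)
        original = sorted(d for _, d in g.degree())
        for rand, method in rewired_replicates(g, 25, seed=0):
            assert method == "rewire"
            assert sorted(d for _, d in rand.degree()) == original

    def test_triangle_rigid_sd_zero_flagged(self):
        net = _net_from_graph(nx.complete_graph(3))
        base = random_baseline(net, n_random=10, seed=0)
        assert base.method == "erdos_renyi"  # no legal swap on a triangle
        assert base.modularity_sd == 0.0
        assert base.GD_sd == 0.0

    def test_modular_fixture_beats_random(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        net = _net_from_graph(g)
        module_detect(net)
        topo = topology_metrics(net)
        base = random_baseline(net, n_random=50, seed=2)
        assert base.modularity_mean < topo.modularity

    def test_too_few_edges(self):
        with pytest.raises(ValueError, match="2 edges"):
            random_baseline(_net_from_graph(nx.Graph([(0, 1)])), n_random=5)


class TestRmtScan:
    def _block_corr(self, n_blocks=4, size=10, within=0.8, seed=0):
        rng = np.random.default_rng(seed)
        n = n_blocks * size
        m = rng.normal(0, 0.05, (n, n))
        m = (m + m.T) / 2
        for b in range(n_blocks):
            sl = slice(b * size, (b + 1) * size)
            m[sl, sl] = within + rng.normal(0, 0.02, (size, size))
            m[sl, sl] = (m[sl, sl] + m[sl, sl].T) / 2
        np.fill_diagonal(m, 1.0)
        ids = [f"t{i}" for i in range(n)]
        return pd.DataFrame(m, index=ids, columns=ids)

    def test_structured_matrix_recommends_below_block_level(self):
        corr = self._block_corr(within=0.8)
        scan = rmt_scan(corr, cutoff_grid=np.arange(0.2, 0.95, 0.05))
        rec = scan.loc[scan["recommended"], "cutoff"]
        assert len(rec) == 1
        assert float(rec.iloc[0]) < 0.8

    def test_identity_like_matrix_poisson_at_low_cutoff(self):
        """With no correlations above the grid, every cutoff is trivially
        Poisson-consistent and the scan recommends the lowest one."""
        rng = np.random.default_rng(3)
        m = rng.normal(0, 0.05, (40, 40))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ids = [f"t{i}" for i in range(40)]
        corr = pd.DataFrame(m, index=ids, columns=ids)
        grid = np.array([0.3, 0.5, 0.7])
        scan = rmt_scan(corr, cutoff_grid=grid)
        rec = scan.loc[scan["recommended"], "cutoff"]
        assert len(rec) == 1 and float(rec.iloc[0]) == pytest.approx(0.3)

    def test_goe_consistency_non_increasing_with_cutoff(self):
        corr = self._block_corr(within=0.8)
        scan = rmt_scan(corr, cutoff_grid=np.array([0.2, 0.9]))
        assert scan["p_goe"].iloc[-1] <= scan["p_goe"].iloc[0]

    def test_small_matrix_error(self):
        corr = self._block_corr(n_blocks=2, size=5)
        with pytest.raises(ValueError, match="20"):
            rmt_scan(corr)


class TestOnSimulatedStudy:
    def test_selection_study_network_pipeline(self, small_selection_study):
        corr, p = spearman_matrix(small_selection_study.table, prevalence_min=0.25)
        net = threshold_network(corr, p, dialect="rho_p", cutoff=0.6, p_max=0.01)
        assert net.graph.number_of_edges() > 2
        modules = module_detect(net)
        topo = topology_metrics(net)
        assert topo.positive_links + topo.negative_links == topo.n_links
        stats = zi_pi(net, modules)
        assert set(stats["role"]) <= {"peripheral", "connector", "module_hub",
                                      "network_hub"}
        assert (stats["keystone"] == ((stats["Zi"] >= 2.5) | (stats["Pi"] >= 0.62))).all()
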