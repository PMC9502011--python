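import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from nitronet import network


class TestSpearmanMatrix:
    @pytest.fixture
    def toy_table(self):
        # 5 samples, one tied value in the second taxon
        return pd.DataFrame(
            {
                "s1": [1.0, 5.0, 9.0],
                "s2": [2.0, 4.0, 7.0],
                "s3": [3.0, 4.0, 5.0],
                "s4": [4.0, 2.0, 3.0],
                "s5": [5.0, 1.0, 1.0],
            },
            index=["up", "down_tied", "down"],
        )

    def test_diagonal_and_bounds(self, toy_table):
        result = network.spearman_matrix(toy_table)
        assert np.allclose(np.diag(result.rho), 1.0)
        off = result.rho.to_numpy()[np.triu_indices(3, 1)]
        assert (np.abs(off) <= 1).all()

    def test_reversed_ranks_give_minus_one(self, toy_table):
        result = network.spearman_matrix(toy_table)
        assert result.rho.loc["up", "down"] == pytest.approx(-1.0)

    def test_matches_hand_ranked_oracle_with_ties(self, toy_table):
        # Spearman = Pearson on average ranks, computed independently
        x = rankdata(toy_table.loc["up"])
        y = rankdata(toy_table.loc["down_tied"])
        expected = np.corrcoef(x, y)[0, 1]
        result = network.spearman_matrix(toy_table)
        assert result.rho.loc["up", "down_tied"] == pytest.approx(expected)

    def test_constant_taxon_recorded_missing(self, toy_table):
        table = toy_table.copy()
        table.loc["flat"] = 2.0
        result = network.spearman_matrix(table)
        assert np.isnan(result.rho.loc["flat", "up"])
        graph = network.build_network(result, threshold=0.1, q_cut=1.0)
        assert graph.degree("flat") == 0

    def test_too_few_samples_rejected(self, toy_table):
        with pytest.raises(ValueError):
            network.spearman_matrix(toy_table.iloc[:, :3])

    def test_q_at_least_p(self, toy_table):
        result = network.spearman_matrix(toy_table)
        iu = np.triu_indices(3, 1)
        assert (result.q.to_numpy()[iu] >= result.p.to_numpy()[iu] - 1e-12).all()


class TestFdrAdjust:
    def test_all_ones_stay_ones(self):
        q, mask = network.fdr_adjust([1.0, 1.0, 1.0], q_cut=0.05)
        assert (q == 1.0).all() and not mask.any()

    def test_single_p_unchanged(self):
        q, _ = network.fdr_adjust([0.013])
        assert q[0] == pytest.approx(0.013)

    def test_bh_step_up_hand_example(self):
        # p = (0.01, 0.02, 0.03, 0.04): q_i = min over j>=i of p_j * m / j
        q, mask = network.fdr_adjust([0.01, 0.02, 0.03, 0.04], q_cut=0.05)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert mask.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            network.fdr_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            network.fdr_adjust([0.5], method="unknown")


class TestRmtThreshold:
    def test_identity_matrix_reports_no_transition(self):
        identity = pd.DataFrame(np.eye(30))
        with pytest.raises(ValueError, match="grid"):
            network.rmt_threshold(identity, grid=np.arange(0.1, 0.9, 0.05))

    def test_block_structure_selects_interior_threshold(self, block_correlation):
        rho, _ = block_correlation(seed=1)
        grid = np.round(np.arange(0.05, 0.91, 0.01), 2)
        selected, diagnostics = network.rmt_threshold(rho, grid=grid)
        assert 0.1 < selected < 0.9
        row = diagnostics[diagnostics["threshold"] == selected].iloc[0]
        assert row["poisson_consistent"]

    def test_nnsd_poisson_at_block_isolating_cutoff(self, block_correlation):
        # at t = 0.5 only the within-block entries survive: union of
        # independent block spectra, hence Poisson spacing
        rho, _ = block_correlation(seed=2)
        truncated = np.where(np.abs(rho.to_numpy()) >= 0.5, rho.to_numpy(), 0.0)
        np.fill_diagonal(truncated, 1.0)
        spacings = network._unfolded_spacings(np.linalg.eigvalsh(truncated), 5)
        _, p = network._poisson_chi2(spacings)
        assert p > 0.05

    def test_dense_noise_matrix_rejects_poisson(self):
        # GOE regime: a sample correlation matrix of pure noise at a
        # negligible cutoff shows level repulsion, not Poisson spacing
        rng = np.random.default_rng(0)
        corr = np.corrcoef(rng.normal(size=(60, 250)))
        truncated = np.where(np.abs(corr) >= 0.01, corr, 0.0)
        np.fill_diagonal(truncated, 1.0)
        spacings = network._unfolded_spacings(np.linalg.eigvalsh(truncated), 5)
        _, p = network._poisson_chi2(spacings)
        assert p < 0.05

    def test_bad_grid_rejected(self, block_correlation):
        rho, _ = block_correlation()
        with pytest.raises(ValueError):
            network.rmt_threshold(rho, grid=[0.5, 0.4])
        with pytest.raises(ValueError):
            network.rmt_threshold(rho, grid=[0.0, 0.5])


def _toy_correlation():
    taxa = ["a", "b", "c", "d"]
    rho = pd.DataFrame(
        [
            [1.0, 0.9, 0.1, -0.8],
            [0.9, 1.0, 0.2, -0.1],
            [0.1, 0.2, 1.0, 0.3],
            [-0.8, -0.1, 0.3, 1.0],
        ],
        index=taxa,
        columns=taxa,
    )
    p = pd.DataFrame(np.full((4, 4), 1e-6), index=taxa, columns=taxa)
    return network.CorrelationResult(rho, p, p.copy())


class TestBuildNetwork:
    def test_toy_edges_and_signs(self):
        graph = network.build_network(_toy_correlation(), threshold=0.7, q_cut=0.05)
        assert set(map(frozenset, graph.edges)) == {
            frozenset({"a", "b"}),
            frozenset({"a", "d"}),
        }
        assert graph.edges["a", "b"]["sign"] == 1
        assert graph.edges["a", "d"]["sign"] == -1
        assert graph.nodes["c"]["isolated"]

    def test_threshold_one_without_perfect_correlation_is_edgeless(self):
        graph = network.build_network(_toy_correlation(), threshold=1.0, q_cut=0.05)
        assert graph.number_of_edges() == 0

    def test_edge_set_monotone_in_threshold_and_qcut(self, block_correlation):
        rho, _ = block_correlation(seed=3, n_taxa=20, n_blocks=2)
        q = pd.DataFrame(
            np.abs(rho.to_numpy()) * 0 + 0.01, index=rho.index, columns=rho.columns
        )
        corr = network.CorrelationResult(rho, q.copy(), q)
        previous = None
        for t in (0.2, 0.5, 0.8):
            edges = set(map(frozenset, network.build_network(corr, t, 0.05).edges))
            if previous is not None:
                assert edges <= previous
            previous = edges
        loose = set(map(frozenset, network.build_network(corr, 0.5, 0.05).edges))
        tight = set(map(frozenset, network.build_network(corr, 0.5, 0.001).edges))
        assert tight <= loose


class TestDetectModules:
    def test_two_disconnected_cliques_are_two_modules(self):
        graph = nx.Graph()
        for offset in (0, 4):
            for i, j in itertools.combinations(range(offset, offset + 4), 2):
                graph.add_edge(f"n{i}", f"n{j}", rho=0.9, sign=1, weight=0.9, q=0.0)
        partition = network.detect_modules(graph, seed=0)
        assert len(set(partition.module_of)) == 2
        first = {f"n{i}" for i in range(4)}
        modules = partition.module_of
        assert len(set(modules[list(first)])) == 1
        assert len(set(modules[[f"n{i}" for i in range(4, 8)]])) == 1

    def test_modularity_matches_formula_and_is_optimal_on_toy(self):
        # 6-node barbell: brute-force all partitions for max modularity
        graph = nx.Graph()
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
        for i, j in edges:
            graph.add_edge(f"n{i}", f"n{j}", rho=1.0, sign=1, weight=1.0, q=0.0)
        partition = network.detect_modules(graph, seed=0)

        def modularity_formula(assignment: dict) -> float:
            m = graph.number_of_edges()
            q_sum = 0.0
            for u in graph.nodes:
                for v in graph.nodes:
                    if assignment[u] != assignment[v]:
                        continue
                    a = 1.0 if graph.has_edge(u, v) else 0.0
                    q_sum += a - graph.degree(u) * graph.degree(v) / (2 * m)
            return q_sum / (2 * m)

        assert partition.modularity == pytest.approx(
            modularity_formula(partition.module_of.to_dict()), abs=1e-9
        )
        nodes = list(graph.nodes)
        best = max(
            modularity_formula(dict(zip(nodes, labels)))
            for labels in itertools.product(range(3), repeat=len(nodes))
        )
        assert partition.modularity == pytest.approx(best, abs=1e-9)

    def test_deterministic_under_fixed_seed(self, block_correlation):
        rho, _ = block_correlation(seed=4)
        q = pd.DataFrame(np.zeros_like(rho), index=rho.index, columns=rho.columns)
        corr = network.CorrelationResult(rho, q.copy(), q)
        graph = network.build_network(corr, 0.5, 1.0)
        a = network.detect_modules(graph, seed=7)
        b = network.detect_modules(graph, seed=7)
        pd.testing.assert_series_equal(a.module_of, b.module_of)
        assert a.modularity == b.modularity

    def test_edgeless_network_rejected(self):
        graph = nx.Graph()
        graph.add_nodes_from(["a", "b"])
        with pytest.raises(ValueError):
            network.detect_modules(graph)


class TestModuleAbundanceAndStats:
    def test_single_module_sums_to_one(self):
        rel = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.2, 0.8]}, index=["a", "b"])
        partition = network.ModulePartition(
            pd.Series({"a": "Mod1", "b": "Mod1"}), modularity=0.0
        )
        out = network.module_abundance(partition, rel)
        assert np.allclose(out.loc["Mod1"], 1.0)

    def test_toy_two_modules_hand_sums(self):
        rel = pd.DataFrame(
            {"s1": [0.1, 0.2, 0.3, 0.4], "s2": [0.4, 0.3, 0.2, 0.1]},
            index=["a", "b", "c", "d"],
        )
        partition = network.ModulePartition(
            pd.Series({"a": "Mod1", "b": "Mod1", "c": "Mod2", "d": "Mod2"}), 0.0
        )
        out = network.module_abundance(partition, rel)
        assert out.loc["Mod1", "s1"] == pytest.approx(0.3)
        assert out.loc["Mod2", "s2"] == pytest.approx(0.3)
        assert (out.sum(axis=0) <= 1 + 1e-12).all()

    def test_missing_taxa_rejected(self):
        rel = pd.DataFrame({"s1": [1.0]}, index=["a"])
        partition = network.ModulePartition(pd.Series({"a": "Mod1", "zz": "Mod1"}), 0.0)
        with pytest.raises(ValueError):
            network.module_abundance(partition, rel)

    def test_stats_on_toy_graph_match_hand_tally(self):
        graph = network.build_network(_toy_correlation(), threshold=0.7, q_cut=0.05)
        stats = network.network_stats(graph)
        assert stats == {
            "n_nodes": 4,
            "n_edges": 2,
            "n_positive_edges": 1,
            "n_negative_edges": 1,
            "mean_degree": 1.0,
            "n_isolated": 1,
        }

    def test_complete_graph_edge_count(self):
        graph = nx.complete_graph(6)
        nx.set_edge_attributes(graph, 1, "sign")
        assert network.network_stats(graph)["n_edges"] == 15
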