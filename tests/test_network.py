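import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cncnet import (PipelineConfig, SyntheticConfig, build_cnc_network,
                    diffk, export_network, generate_annotation,
                    generate_expression, k_core_decomposition, pearson)

from conftest import make_matrix


def core_numbers_by_pruning(graph):
    """Independent oracle: repeatedly delete nodes of degree < k."""
    core = {n: 0 for n in graph.nodes}
    k = 1
    while True:
        g = graph.copy()
        while True:
            weak = [n for n in g.nodes if g.degree(n) < k]
            if not weak:
                break
            g.remove_nodes_from(weak)
        if g.number_of_nodes() == 0:
            return core
        for n in g.nodes:
            core[n] = k
        k += 1


class TestPearson:
    def test_exact_linear(self):
        assert pearson([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]) == pytest.approx(1.0)

    def test_reflection(self):
        assert pearson([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="size >= 3"):
            pearson([1, 2], [3, 4])


class TestBuildNetwork:
    def _toy_matrix(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        rows = [a, a + 0.001 * rng.standard_normal(10),
                b, -b + 0.001 * rng.standard_normal(10),
                rng.standard_normal(10)]
        return make_matrix(rows, gene_ids=["l1", "m1", "l2", "m2", "m3"])

    def test_planted_duplicates_found_exactly(self, pipeline_config):
        m = self._toy_matrix()
        net = build_cnc_network(m, "disease", ["l1", "l2"],
                                ["m1", "m2", "m3"], pipeline_config)
        assert set(map(frozenset, net.edges)) == {frozenset(("l1", "m1")),
                                                  frozenset(("l2", "m2"))}
        assert net.edges["l1", "m1"]["sign"] == "+"
        assert net.edges["l2", "m2"]["sign"] == "-"
        assert "m3" not in net  # zero-degree candidates are dropped

    def test_matches_exhaustive_all_pairs_oracle(self, pipeline_config):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.standard_normal((30, 10)))
        genes = m.gene_ids
        net = build_cnc_network(m, "disease", genes[:10], genes[10:],
                                pipeline_config.replace(corr_threshold=0.5))
        vals = m.group_values("disease")
        want = set()
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                r = np.corrcoef(vals.loc[a], vals.loc[b])[0, 1]
                if abs(r) >= 0.5:
                    want.add(frozenset((a, b)))
        assert set(map(frozenset, net.edges)) == want

    def test_signed_threshold_excludes_negative_edges(self, pipeline_config):
        m = self._toy_matrix()
        cfg = pipeline_config.replace(corr_use_absolute=False)
        net = build_cnc_network(m, "disease", ["l1", "l2"], ["m1", "m2"], cfg)
        assert all(d["sign"] == "+" for _, _, d in net.edges(data=True))

    def test_bipartite_switch_drops_same_biotype_edges(self, pipeline_config):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(10)
        m = make_matrix([a, a + 1, a + 2], gene_ids=["l1", "l2", "m1"])
        cfg = pipeline_config.replace(bipartite_only=True)
        net = build_cnc_network(m, "disease", ["l1", "l2"], ["m1"], cfg)
        assert set(map(frozenset, net.edges)) == {frozenset(("l1", "m1")),
                                                  frozenset(("l2", "m1"))}

    def test_uncorrelated_noise_gives_empty_network(self, pipeline_config):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.standard_normal((40, 10)))
        net = build_cnc_network(m, "control", m.gene_ids[:20],
                                m.gene_ids[20:], pipeline_config)
        # at n=5 a spurious |r| >= 0.97 has probability ~1%; 780 pairs can
        # produce a few edges but nothing resembling a module
        assert net.number_of_edges() < 30

    def test_sample_order_invariance(self, pipeline_config):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.standard_normal((12, 8)))
        cfg = pipeline_config.replace(corr_threshold=0.5)
        net1 = build_cnc_network(m, "disease", m.gene_ids[:6], m.gene_ids[6:], cfg)
        shuffled = m.values[["d1", "d3", "d0", "d2", "c0", "c1", "c2", "c3"]]
        m2 = type(m)(shuffled, m.groups)
        net2 = build_cnc_network(m2, "disease", m.gene_ids[:6], m.gene_ids[6:], cfg)
        assert set(map(frozenset, net1.edges)) == set(map(frozenset, net2.edges))

    def test_too_few_samples_rejected(self, pipeline_config):
        m = make_matrix(np.random.default_rng(5).standard_normal((4, 4)))
        with pytest.raises(ValueError, match=">= 3"):
            build_cnc_network(m, "disease", m.gene_ids[:2], m.gene_ids[2:],
                              pipeline_config)


class TestKCore:
    def test_triangle(self):
        g = nx.cycle_graph(3)
        assert k_core_decomposition(g) == {0: 2, 1: 2, 2: 2}

    def test_triangle_with_pendant(self):
        g = nx.cycle_graph(3)
        g.add_edge(2, 3)
        assert k_core_decomposition(g) == {0: 2, 1: 2, 2: 2, 3: 1}

    def test_empty_graph(self):
        assert k_core_decomposition(nx.Graph()) == {}

    def test_matches_pruning_oracle_on_random_graphs(self):
        for seed in range(100):
            g = nx.gnp_random_graph(30, 0.2, seed=seed)
            assert k_core_decomposition(g) == core_numbers_by_pruning(g)

    def test_degree_bounds_core_index(self):
        g = nx.gnp_random_graph(50, 0.15, seed=7)
        core = k_core_decomposition(g)
        assert all(g.degree(n) >= core[n] for n in g.nodes)


class TestDiffK:
    def _net(self, edges, group):
        g = nx.Graph(group=group)
        for a, b in edges:
            g.add_node(a, biotype="lncRNA" if a.startswith("l") else "mRNA")
            g.add_node(b, biotype="lncRNA" if b.startswith("l") else "mRNA")
            g.add_edge(a, b, r=0.99, sign="+")
        return g

    def test_unique_hub_absent_in_control_scores_one(self, pipeline_config):
        net_d = self._net([("l1", "m1"), ("l1", "m2"), ("l1", "m3"),
                           ("m1", "m2")], "disease")
        net_c = self._net([("m1", "m2")], "control")
        table = diffk(net_d, net_c, pipeline_config)
        assert table.index[0] == "l1"
        assert table.at["l1", "diffK"] == pytest.approx(1.0)
        assert table.at["l1", "K_control"] == 0.0

    def test_identical_networks_score_zero(self, pipeline_config):
        net = self._net([("l1", "m1"), ("m1", "m2")], "disease")
        table = diffk(net, net, pipeline_config)
        assert (table["diffK"] == 0).all()

    def test_antisymmetry(self, pipeline_config):
        rng = np.random.default_rng(8)
        e1 = [(f"m{i}", f"m{j}") for i in range(8) for j in range(i + 1, 8)
              if rng.random() < 0.3]
        e2 = [(f"m{i}", f"m{j}") for i in range(8) for j in range(i + 1, 8)
              if rng.random() < 0.3]
        a = diffk(self._net(e1, "disease"), self._net(e2, "control"),
                  pipeline_config)
        b = diffk(self._net(e2, "disease"), self._net(e1, "control"),
                  pipeline_config)
        merged = a["diffK"].sort_index() + b["diffK"].sort_index()
        assert np.allclose(merged, 0.0)

    def test_both_empty_warns_and_returns_empty(self, pipeline_config):
        with pytest.warns(UserWarning, match="empty"):
            table = diffk(nx.Graph(), nx.Graph(), pipeline_config)
        assert table.empty

    def test_n_minus_1_normalization(self, pipeline_config):
        net_d = self._net([("l1", "m1"), ("l1", "m2")], "disease")
        cfg = pipeline_config.replace(k_normalization="n_minus_1")
        table = diffk(net_d, nx.Graph(), cfg)
        assert table.at["l1", "K_disease"] == pytest.approx(1.0)
        assert table.at["m1", "K_disease"] == pytest.approx(0.5)

    def test_planted_differential_hub_ranks_first(self, pipeline_config):
        wins = 0
        for seed in range(30):
            cfg = SyntheticConfig(
                n_mrna=60, n_lnc=15, frac_de=0.0,
                n_planted_pairs_per_category=0, n_modules=1, module_size=10,
                hub_corr_disease=0.99, hub_corr_control=0.3,
                n_chromosomes=4, chrom_length=10_000_000, seed=seed)
            ann, _ = generate_annotation(cfg)
            matrix, truth = generate_expression(ann, cfg)
            bt = ann.df.set_index("id")["biotype"]
            de = sorted(truth.de_genes)
            net_d = build_cnc_network(
                matrix, "disease", [g for g in de if bt[g] == "lncRNA"],
                [g for g in de if bt[g] == "mRNA"], pipeline_config)
            net_c = build_cnc_network(
                matrix, "control", [g for g in de if bt[g] == "lncRNA"],
                [g for g in de if bt[g] == "mRNA"], pipeline_config)
            table = diffk(net_d, net_c, pipeline_config)
            wins += len(table) > 0 and table.index[0] == truth.hub_ids[0]
        assert wins >= 29


class TestExport:
    def test_sif_and_graphml_round_trip(self, tmp_path, pipeline_config):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(10)
        m = make_matrix([a, a + 0.001 * rng.standard_normal(10), a + 1],
                        gene_ids=["l1", "m1", "m2"])
        net = build_cnc_network(m, "disease", ["l1"], ["m1", "m2"],
                                pipeline_config)
        stats = diffk(net, nx.Graph(), pipeline_config)
        export_network(net, stats, tmp_path / "n.sif", tmp_path / "n.graphml")
        sif_lines = (tmp_path / "n.sif").read_text().strip().splitlines()
        assert len(sif_lines) == net.number_of_edges()
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert set(back.nodes) == set(net.nodes)
        assert {frozenset(e) for e in back.edges} == \
            {frozenset(e) for e in net.edges}
        assert back.nodes["l1"]["biotype"] == "lncRNA"
        assert back.nodes["l1"]["diffK"] == pytest.approx(
            stats.at["l1", "diffK"])

    def test_empty_network_valid_graphml(self, tmp_path):
        export_network(nx.Graph(group="disease"), None,
                       tmp_path / "e.sif", tmp_path / "e.graphml")
        assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0
        assert (tmp_path / "e.sif").read_text() == ""
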