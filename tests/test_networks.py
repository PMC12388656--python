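"""Co-occurrence / taxon-environment networks and topology metrics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import assemblyscape as asc
from assemblyscape import CommunityTable, correlation_network, select_taxa, taxon_env_network
from assemblyscape.networks import NetworkGraph, topology


def genus_table(counts, genera=None, phyla=None, samples=None):
    counts = np.asarray(counts)
    n_s, n_t = counts.shape
    samples = samples or [f"s{i}" for i in range(n_s)]
    taxa = [f"otu{j}" for j in range(n_t)]
    genera = genera or [f"g{j}" for j in range(n_t)]
    phyla = phyla or ["P1"] * n_t
    md = pd.DataFrame({"site": samples, "layer": "T", "grassland": "AM"},
                      index=samples)
    tax = pd.DataFrame({"phylum": phyla, "genus": genera},
                       index=pd.Index(taxa, name="taxon"))
    return CommunityTable(pd.DataFrame(counts, index=samples, columns=taxa),
                          md, tax)


class TestSelectTaxa:
    def test_rare_phylum_dropped(self):
        # phylum P2 carries <1% of reads everywhere
        counts = np.array([[500, 490, 4], [480, 515, 5], [505, 492, 3]])
        t = genus_table(counts, phyla=["P1", "P1", "P2"])
        sel = select_taxa(t)
        assert "g2" not in sel.taxa
        assert set(sel.taxa) == {"g0", "g1"}

    def test_cap_not_binding(self):
        rng = np.random.default_rng(0)
        t = genus_table(rng.integers(1, 50, (5, 20)))
        sel = select_taxa(t, top_n=200)
        assert sel.n_taxa == 20

    def test_hand_ranked_selection(self):
        """Genus ranks engineered by construction match the selection."""
        counts = np.tile([100, 80, 60, 40, 20, 10], (4, 1))
        t = genus_table(counts)
        sel = select_taxa(t, top_n=3)
        assert sel.taxa == ["g0", "g1", "g2"]

    def test_genus_aggregation(self):
        counts = np.array([[10, 5, 1], [2, 8, 4]])
        t = genus_table(counts, genera=["gA", "gA", "gB"])
        sel = select_taxa(t)
        assert sorted(sel.taxa) == ["gA", "gB"]
        assert sel.counts["gA"].tolist() == [15, 10]


class TestCorrelationNetwork:
    def test_perfect_monotone_pairs(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 50, 10)
        counts = np.column_stack([base, 2 * base, 51 - base,
                                  rng.integers(1, 50, 10)])
        t = genus_table(counts)
        net = correlation_network(select_taxa(t), rho_min=0.8, p_max=0.05)
        g = net.graph
        assert g.edges[("g0", "g1")]["sign"] == "positive"
        assert g.edges[("g0", "g2")]["sign"] == "negative"
        assert g.edges[("g0", "g1")]["rho"] == pytest.approx(1.0)

    def test_constant_genus_excluded(self):
        counts = np.column_stack([np.arange(1, 9), np.full(8, 5),
                                  np.arange(8, 0, -1)])
        t = genus_table(counts)
        with pytest.warns(UserWarning, match="constant"):
            net = correlation_network(select_taxa(t))
        assert "g1" not in net.graph.nodes

    def test_rank_invariance_under_monotone_transform(self):
        """Edges depend only on abundance ranks (Spearman invariance)."""
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 100, (12, 6))
        t1 = genus_table(counts)
        t2 = genus_table(counts ** 2)
        e1 = correlation_network(select_taxa(t1)).edges[["source", "target", "rho"]]
        e2 = correlation_network(select_taxa(t2)).edges[["source", "target", "rho"]]
        pd.testing.assert_frame_equal(e1, e2)


class TestTopology:
    def _net(self, g):
        return NetworkGraph(graph=g, edges=pd.DataFrame())

    def test_complete_graph_identities(self):
        top = topology(self._net(nx.complete_graph(4)))
        assert top["clustering_coefficient"] == pytest.approx(1.0)
        assert top["average_degree"] == pytest.approx(3.0)
        assert top["average_path_length"] == pytest.approx(1.0)

    def test_path_graph_hand_values(self):
        top = topology(self._net(nx.path_graph(3)))
        assert top["clustering_coefficient"] == 0.0
        assert top["average_path_length"] == pytest.approx(4 / 3)

    def test_two_cliques_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        q = nx.community.modularity(g, [set(range(5)), set(range(5, 10))])
        assert q == pytest.approx(0.5)
        top = topology(self._net(g))
        assert top["modularity"] >= 0.5 - 1e-9

    def test_empty_graph_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            top = topology(self._net(nx.Graph()))
        assert top["modularity"] == 0.0

    def test_positive_edge_fraction_all_positive(self):
        rng = np.random.default_rng(5)
        base = rng.integers(5, 40, 10)
        # two genera track a shared driver; four noise genera absorb the
        # compositional closure so no strong negative pair arises
        counts = np.column_stack(
            [base * 20 + rng.integers(0, 3, 10),
             base * 16 + rng.integers(0, 3, 10)]
            + [rng.integers(50, 150, 10) for _ in range(4)])
        net = correlation_network(select_taxa(genus_table(counts)),
                                  rho_min=0.9)
        assert net.graph.number_of_edges() >= 1
        assert net.topology["positive_edge_fraction"] == 1.0


class TestTaxonEnvNetwork:
    def test_soc_tracking_genus_positive_edge(self):
        rng = np.random.default_rng(6)
        soc = np.linspace(5, 25, 10) + rng.normal(0, 0.1, 10)
        counts = np.column_stack([
            np.round(soc * 10).astype(int),
            np.full(10, 120),  # flat denominator keeps rel(g0) monotone in SOC
        ])
        t = genus_table(counts)
        env = pd.DataFrame({"SOC": soc, "pH": rng.normal(7, 0.2, 10)},
                           index=t.samples)
        net = taxon_env_network(select_taxa(t), env, rho_min=0.8, p_max=0.01)
        assert net.graph.has_edge("g0", "SOC")
        assert net.graph.edges[("g0", "SOC")]["sign"] == "positive"

    def test_constant_env_variable_excluded(self):
        rng = np.random.default_rng(7)
        t = genus_table(rng.integers(1, 30, (8, 3)))
        env = pd.DataFrame({"SOC": rng.normal(10, 2, 8),
                            "BD": np.full(8, 1.3)}, index=t.samples)
        with pytest.warns(UserWarning, match="constant"):
            net = taxon_env_network(select_taxa(t), env)
        assert "BD" not in net.graph.nodes

    def test_map_dominates_when_niches_track_map(self):
        """Variable-selection data along the precipitation gradient: MAP has
        the highest bipartite degree among environment variables."""
        cfg = asc.SimConfig(n_taxa=300, n_sites=24, n_layers=1,
                            reads_per_sample=1500,
                            regime="variable_selection", sigma=0.3,
                            within_noise=0.5, seed=31)
        table, _, env, _ = asc.simulate_dataset(cfg)
        genus = select_taxa(table.drop_empty_taxa(), top_n=100)
        net = taxon_env_network(genus, env, rho_min=0.6, p_max=0.01)
        deg = {v: d for v, d in net.graph.degree()
               if net.graph.nodes[v].get("kind") == "environment"}
        assert max(deg, key=deg.get) in ("MAP", "MAT", "latitude", "EC")
        assert deg.get("MAP", 0) >= max(
            d for v, d in deg.items() if v in ("SOC", "TP", "AP", "BD"))
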