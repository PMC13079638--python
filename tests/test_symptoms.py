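import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ohsurvey import (
    cooccurrence_network,
    item_prevalence,
    network_metrics,
    severity_scores,
    system_prevalence,
    system_scores,
    total_symptom_burden,
)
from ohsurvey.symptoms import SymptomNetwork

from conftest import hub_and_filler_symptoms


def frame(columns, rows):
    return pd.DataFrame(rows, columns=columns)


class TestPrevalenceAndSeverity:
    def test_all_zero_matrix(self):
        m = pd.DataFrame(np.zeros((62, 66), dtype=int))
        assert (item_prevalence(m)["prevalence"] == 0).all()

    def test_prevalence_counting(self):
        col = np.zeros(62, dtype=int)
        col[:28] = 1
        m = pd.DataFrame({"memory_impairment": col})
        out = item_prevalence(m)
        assert out.loc[0, "n_positive"] == 28
        assert out.loc[0, "prevalence"] == pytest.approx(28 / 62)  # 45.2%

    def test_saturated_column(self):
        m = pd.DataFrame({"x": [3, 3, 3]})
        assert item_prevalence(m)["prevalence"].iloc[0] == 1.0

    def test_severity_is_symptomatic_only_mean(self):
        m = frame(["a", "b"], [[1, 1], [2, 1], [3, 1], [0, 0]])
        s = severity_scores(m)
        assert s["a"] == pytest.approx(2.0)
        assert s["b"] == pytest.approx(1.0)

    def test_severity_undefined_warns(self):
        m = frame(["a"], [[0], [0]])
        with pytest.warns(UserWarning, match="no reporters"):
            s = severity_scores(m)
        assert math.isnan(s["a"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="no respondents"):
            item_prevalence(pd.DataFrame({"a": []}))


class TestSystemPrevalence:
    def test_single_symptom_counts_once(self, codebook):
        m = pd.DataFrame(
            np.zeros((3, 66), dtype=int), columns=codebook.section_ids("symptom")
        )
        m.loc[0, "memory_impairment"] = 1
        out = system_prevalence(m, codebook).set_index("system")
        assert out.loc["neurological", "n_affected"] == 1
        assert (out.drop(index="neurological")["n_affected"] == 0).all()

    def test_two_symptoms_same_system_idempotent(self, codebook):
        m = pd.DataFrame(
            np.zeros((3, 66), dtype=int), columns=codebook.section_ids("symptom")
        )
        m.loc[0, ["memory_impairment", "insomnia"]] = [1, 3]
        out = system_prevalence(m, codebook).set_index("system")
        assert out.loc["neurological", "n_affected"] == 1

    def test_constructed_prevalence_fraction(self, codebook):
        # 42 of 62 respondents with >= 1 neurological symptom -> 67.7%
        m = pd.DataFrame(
            np.zeros((62, 66), dtype=int), columns=codebook.section_ids("symptom")
        )
        m.loc[:41, "headache"] = 1
        out = system_prevalence(m, codebook).set_index("system")
        assert out.loc["neurological", "prevalence"] == pytest.approx(0.677, abs=5e-4)


class TestBurden:
    def test_row_sums(self):
        m = frame(list("abc"), [[0, 0, 0], [1, 2, 3], [3, 3, 3]])
        assert total_symptom_burden(m).tolist() == [0, 6, 9]

    def test_burden_conserved_across_systems(self, cohort, codebook):
        tsb = total_symptom_burden(cohort.symptoms)
        by_system = system_scores(cohort.symptoms, codebook).sum(axis=1)
        assert (tsb == by_system).all()


class TestCooccurrenceNetwork:
    def test_retention_count_uses_ceiling(self):
        # 5 items pairwise co-occurring -> 10 candidate edges; keep ceil(3.0)=3
        m = pd.DataFrame(np.ones((4, 5), dtype=int), columns=list("abcde"))
        m.iloc[0, 0] = 0
        net = cooccurrence_network(m, node_min_prevalence=0.0, edge_quantile=0.30)
        assert net.n_edges == 3

    def test_always_copresent_triangle(self):
        m = pd.DataFrame(np.ones((5, 3), dtype=int), columns=list("abc"))
        net = cooccurrence_network(m, node_min_prevalence=0.0, edge_quantile=1.0)
        assert net.metrics["density"] == pytest.approx(1.0)
        assert net.metrics["average_clustering"] == pytest.approx(1.0)
        assert net.metrics["average_degree"] == pytest.approx(2.0)

    def test_thirteen_node_fixture(self):
        net = cooccurrence_network(
            hub_and_filler_symptoms(), node_min_prevalence=0.0, edge_quantile=0.30
        )
        assert (net.n_nodes, net.n_edges) == (13, 26)
        assert net.metrics["density"] == pytest.approx(1 / 3, abs=5e-4)
        assert net.metrics["average_degree"] == pytest.approx(4.0)
        assert all(n.startswith("core_") for n in net.graph.nodes)

    def test_node_prevalence_threshold(self):
        m = frame(["rare", "common1", "common2"],
                  [[1, 1, 1]] + [[0, 1, 1]] * 9)
        net = cooccurrence_network(m, node_min_prevalence=0.2, edge_quantile=1.0)
        assert set(net.graph.nodes) == {"common1", "common2"}

    def test_edge_weight_bounded_by_node_counts(self, cohort):
        net = cooccurrence_network(cohort.symptoms, node_min_prevalence=0.2,
                                   edge_quantile=1.0)
        for a, b, d in net.graph.edges(data=True):
            assert d["weight"] <= min(net.node_counts[a], net.node_counts[b])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_quantile_filter_is_nested(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.integers(0, 3, size=(30, 12)))
        m.columns = [f"s{j}" for j in range(12)]
        previous: set = set()
        for q in (0.1, 0.3, 0.5, 0.8, 1.0):
            net = cooccurrence_network(m, node_min_prevalence=0.0, edge_quantile=q)
            edges = {tuple(sorted(e)) for e in net.graph.edges}
            assert previous <= edges
            previous = edges

    def test_fewer_than_two_candidates_warns_empty(self):
        m = frame(["a", "b"], [[1, 0]] * 10)
        with pytest.warns(UserWarning, match="fewer than 2"):
            net = cooccurrence_network(m, node_min_prevalence=0.5)
        assert net.n_nodes == 0

    def test_invalid_quantile_rejected(self):
        m = pd.DataFrame(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="edge_quantile"):
            cooccurrence_network(m, edge_quantile=1.5)


class TestNetworkMetrics:
    def test_path_graph(self):
        g = nx.path_graph(["a", "b", "c"])
        metrics, centrality = network_metrics(g)
        assert metrics["density"] == pytest.approx(2 / 3)
        assert metrics["average_degree"] == pytest.approx(4 / 3)
        assert metrics["average_clustering"] == 0.0

    def test_star_betweenness(self):
        g = nx.star_graph(4)  # hub 0 with 4 leaves
        _, centrality = network_metrics(g)
        hub = centrality.set_index("item").loc[0]
        assert hub["betweenness"] == pytest.approx(1.0)
        leaves = centrality[centrality["item"] != 0]
        assert (leaves["betweenness"] == 0).all()

    def test_identities_hold_for_generated_network(self, cohort):
        net = cooccurrence_network(cohort.symptoms)
        n, e = net.n_nodes, net.n_edges
        assert net.metrics["density"] == pytest.approx(2 * e / (n * (n - 1)))
        assert net.metrics["average_degree"] == pytest.approx(2 * e / n)

    def test_tiny_graph_metrics_null(self):
        metrics, centrality = network_metrics(nx.Graph())
        assert metrics["density"] is None
        assert centrality is None


def test_network_export_round_trips(tmp_path, cohort):
    from ohsurvey.symptoms import export_network

    net = cooccurrence_network(cohort.symptoms)
    files = export_network(net, tmp_path, layout_seed=42)
    assert set(files) == {"network.graphml", "network_edges.csv",
                          "network_metrics.json"}
    back = nx.read_graphml(tmp_path / "network.graphml")
    assert back.number_of_edges() == net.n_edges
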