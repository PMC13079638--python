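"""Symptom prevalence, severity, burden, and the co-occurrence network.

Presence of a symptom means a severity code >= 1 (the scale defines 0 as
"none"). Per-item prevalence Pi is the fraction of respondents reporting the
symptom; the severity score S̄j is the mean code among respondents reporting
it (symptomatic-only mean); per-system prevalence counts a respondent once if
any item of that system is present; the total symptom burden TSB is the row
sum of severity codes.

The co-occurrence network has one node per sufficiently prevalent symptom and
one edge per symptom pair weighted by the number of respondents reporting
both; only the top 30% of candidate edges by co-occurrence count (ceiling,
deterministic tie-break) are retained, and nodes isolated by the filter are
dropped.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .instrument import Codebook


@dataclass
class SymptomSummary:
    per_item: pd.DataFrame       # item, n_positive, prevalence, severity
    per_system: pd.DataFrame     # system, n_affected, prevalence
    per_respondent: pd.Series    # TSB


@dataclass
class SymptomNetwork:
    """Undirected simple graph of retained symptom co-occurrences."""

    graph: nx.Graph
    node_counts: dict[str, int]
    metrics: dict = field(default_factory=dict)
    centrality: pd.DataFrame | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": a, "target": b, "weight": int(d["weight"])}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


def _check_symptom_matrix(symptoms: pd.DataFrame) -> np.ndarray:
    values = symptoms.to_numpy()
    if values.shape[0] == 0:
        raise ValueError("symptom matrix has no respondents")
    if np.any((values < 0) | (values > 3)):
        raise ValueError("symptom codes must lie in 0..3")
    return values


def item_prevalence(symptoms: pd.DataFrame) -> pd.DataFrame:
    """Per-item count of reporters and prevalence Pi = n_positive / n."""
    values = _check_symptom_matrix(symptoms)
    n = values.shape[0]
    n_positive = (values >= 1).sum(axis=0)
    return pd.DataFrame(
        {
            "item": symptoms.columns,
            "n_positive": n_positive.astype(int),
            "prevalence": n_positive / n,
        }
    )


def severity_scores(symptoms: pd.DataFrame) -> pd.Series:
    """Mean severity among reporters per item; NaN where nobody reports it."""
    values = _check_symptom_matrix(symptoms).astype(float)
    reported = values >= 1
    counts = reported.sum(axis=0)
    sums = np.where(reported, values, 0.0).sum(axis=0)
    if np.any(counts == 0):
        absent = [c for c, k in zip(symptoms.columns, counts) if k == 0]
        warnings.warn(
            f"severity undefined (no reporters) for {len(absent)} item(s): "
            f"{absent[:5]}{'...' if len(absent) > 5 else ''}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=symptoms.columns, name="severity")


def system_prevalence(symptoms: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Per-system count of affected respondents and prevalence PrevS."""
    values = _check_symptom_matrix(symptoms)
    n = values.shape[0]
    unmapped = [c for c in symptoms.columns if codebook.item(c).section != "symptom"]
    if unmapped:
        raise ValueError(f"columns not mapped to a physiological system: {unmapped}")
    rows = []
    for system in codebook.systems:
        ids = [i for i in codebook.system_item_ids(system) if i in symptoms.columns]
        affected = (symptoms[ids].to_numpy() >= 1).any(axis=1).sum() if ids else 0
        rows.append(
            {"system": system, "n_affected": int(affected), "prevalence": affected / n}
        )
    return pd.DataFrame(rows)


def total_symptom_burden(symptoms: pd.DataFrame) -> pd.Series:
    """Per-respondent sum of severity codes (TSB)."""
    values = _check_symptom_matrix(symptoms)
    return pd.Series(values.sum(axis=1), index=symptoms.index, name="tsb")


def system_scores(symptoms: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Per-respondent, per-system sums of severity codes (n x 10)."""
    _check_symptom_matrix(symptoms)
    out = {
        system: symptoms[codebook.system_item_ids(system)].sum(axis=1)
        for system in codebook.systems
    }
    return pd.DataFrame(out, index=symptoms.index)


def summarize_symptoms(symptoms: pd.DataFrame, codebook: Codebook) -> SymptomSummary:
    per_item = item_prevalence(symptoms)
    per_item["severity"] = severity_scores(symptoms).to_numpy()
    return SymptomSummary(
        per_item=per_item,
        per_system=system_prevalence(symptoms, codebook),
        per_respondent=total_symptom_burden(symptoms),
    )


def cooccurrence_network(
    symptoms: pd.DataFrame,
    codebook: Codebook | None = None,
    node_min_prevalence: float = 0.20,
    edge_quantile: float = 0.30,
) -> SymptomNetwork:
    """Build the retained co-occurrence network.

    Candidate nodes are items with prevalence >= ``node_min_prevalence``;
    candidate edges are item pairs co-reported by at least one respondent.
    The top ``ceil(edge_quantile * n_candidate_edges)`` edges by weight are
    retained (ties broken by larger combined node counts, then by item id),
    and nodes left isolated are dropped.
    """
    if not 0 < edge_quantile <= 1:
        raise ValueError("edge_quantile must lie in (0, 1]")
    values = _check_symptom_matrix(symptoms)
    n = values.shape[0]
    present = values >= 1
    counts = present.sum(axis=0)
    candidate_idx = [
        j for j in range(values.shape[1]) if counts[j] / n >= node_min_prevalence
    ]
    items = list(symptoms.columns)
    if len(candidate_idx) < 2:
        warnings.warn("fewer than 2 candidate nodes; returning empty network",
                      stacklevel=2)
        return SymptomNetwork(graph=nx.Graph(), node_counts={})

    node_counts = {items[j]: int(counts[j]) for j in candidate_idx}
    edges = []
    for ai in range(len(candidate_idx)):
        for bi in range(ai + 1, len(candidate_idx)):
            ja, jb = candidate_idx[ai], candidate_idx[bi]
            w = int(np.sum(present[:, ja] & present[:, jb]))
            if w >= 1:
                a, b = sorted((items[ja], items[jb]))
                edges.append((a, b, w))

    n_keep = math.ceil(edge_quantile * len(edges))
    edges.sort(
        key=lambda e: (-e[2], -(node_counts[e[0]] + node_counts[e[1]]), e[0], e[1])
    )
    retained = edges[:n_keep]

    graph = nx.Graph()
    for a, b, w in retained:
        graph.add_edge(a, b, weight=w)
    for node in graph.nodes:
        graph.nodes[node]["count"] = node_counts[node]

    net = SymptomNetwork(graph=graph, node_counts=node_counts)
    net.metrics, net.centrality = network_metrics(net)
    return net


def network_metrics(network: SymptomNetwork | nx.Graph) -> tuple[dict, pd.DataFrame | None]:
    """Density, average clustering, average degree, and per-node centrality.

    Density = 2E / (N(N-1)); average degree = 2E / N; clustering is the
    unweighted triangle ratio averaged over nodes; betweenness is computed on
    the unweighted retained graph, normalized. All metrics are None for
    graphs with fewer than 2 nodes.
    """
    graph = network.graph if isinstance(network, SymptomNetwork) else network
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    if n_nodes < 2:
        return (
            {"n_nodes": n_nodes, "n_edges": n_edges, "density": None,
             "average_clustering": None, "average_degree": None},
            None,
        )
    degree = dict(graph.degree())
    metrics = {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "density": 2 * n_edges / (n_nodes * (n_nodes - 1)),
        "average_clustering": nx.average_clustering(graph),
        "average_degree": 2 * n_edges / n_nodes,
    }
    betweenness = nx.betweenness_centrality(graph, normalized=True, weight=None)
    degree_centrality = nx.degree_centrality(graph)
    centrality = pd.DataFrame(
        {
            "item": sorted(graph.nodes),
            "degree": [degree[v] for v in sorted(graph.nodes)],
            "degree_centrality": [degree_centrality[v] for v in sorted(graph.nodes)],
            "betweenness": [betweenness[v] for v in sorted(graph.nodes)],
        }
    )
    return metrics, centrality


def export_network(network: SymptomNetwork, out_dir: str | Path,
                   layout_seed: int | None = None) -> list[str]:
    """Write GraphML, an edge-list CSV, and metrics JSON; returns file names.

    ``layout_seed`` optionally adds spring-layout coordinates as node
    attributes for plotting; the layout never affects any metric.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    graph = network.graph.copy()
    if layout_seed is not None and graph.number_of_nodes() > 0:
        pos = nx.spring_layout(graph, seed=layout_seed)
        for node, (x, y) in pos.items():
            graph.nodes[node]["x"] = float(x)
            graph.nodes[node]["y"] = float(y)
    files = []
    nx.write_graphml(graph, out_dir / "network.graphml")
    files.append("network.graphml")
    network.edge_table().to_csv(out_dir / "network_edges.csv", index=False,
                                lineterminator="\n")
    files.append("network_edges.csv")
    (out_dir / "network_metrics.json").write_text(
        json.dumps(network.metrics, indent=1, sort_keys=True) + "\n"
    )
    files.append("network_metrics.json")
    return files
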