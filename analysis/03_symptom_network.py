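"""Build the symptom co-occurrence network (top 30% of edges by weight)."""
from pathlib import Path

from ohsurvey import cooccurrence_network, default_codebook, load_survey
from ohsurvey.symptoms import export_network

OUT = Path(__file__).resolve().parent.parent / "results"
codebook = default_codebook()
cohort = load_survey(OUT / "survey.csv", codebook)

network = cooccurrence_network(
    cohort.symptoms, codebook, node_min_prevalence=0.20, edge_quantile=0.30
)
export_network(network, OUT, layout_seed=42)

m = network.metrics
print(f"retained network: {m['n_nodes']} nodes, {m['n_edges']} edges, "
      f"density {m['density']:.3f}, average degree {m['average_degree']:.2f}, "
      f"average clustering {m['average_clustering']:.3f}")
hubs = network.centrality.sort_values("betweenness", ascending=False).head(3)
print("central hub symptoms (betweenness):")
for row in hubs.itertuples():
    print(f"  {row.item}: betweenness {row.betweenness:.3f}, degree {row.degree}")
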