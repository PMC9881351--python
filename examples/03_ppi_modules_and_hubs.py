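"""Find dense modules and consensus hub genes in a weighted PPI graph.

Builds the score-filtered graph (combined score > 0.4), runs MCODE-style
clustering, ranks nodes by five centralities (MCC, Degree, DMNC, MNC,
clustering coefficient) and intersects the top-14 lists into hub genes.
"""

from neuromarker import (
    SynthConfig,
    build_graph,
    centrality,
    gen_ppi,
    hub_consensus,
    mcode_cluster,
)

cfg = SynthConfig(seed=1)
edges, planted_blocks = gen_ppi(cfg)
graph = build_graph(edges, min_score=0.4)
print(f"filtered graph: {graph.number_of_nodes()} nodes, "
      f"{graph.number_of_edges()} edges")

modules = mcode_cluster(graph)
for i, m in enumerate(modules[:4], 1):
    print(f"module {i}: {m.n_nodes} nodes, {m.n_edges} edges, "
          f"score {m.score:.3f}")

rankings = [
    centrality(graph, method)
    for method in ("MCC", "Degree", "DMNC", "MNC", "ClusteringCoefficient")
]
hubs, _ = hub_consensus(rankings)
print(f"consensus hubs ({len(hubs)}): {sorted(hubs)}")
top = set(modules[0].members)
best = max(len(top & set(b)) / len(top | set(b)) for b in planted_blocks)
print(f"top module vs planted blocks, best Jaccard: {best:.2f}")
# The module score is density x V (density = E/(V(V-1))). The top module
# here merges two planted blocks bridged by background edges — authentic
# seed-and-grow behavior; with a single planted block recovery is clean.
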