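"""Assemble a tripartite ceRNA (mRNA-miRNA-lncRNA/circRNA) network.

Target miRNAs are kept when predicted by >= 4 of 5 sources; ncRNA
interactions need CLIP support >= 5; circRNA isoforms of one transcript
collapse to the best-supported one; an ncRNA joins the network only when it
sponges a strict majority of a gene's consensus miRNAs.
"""

from neuromarker import (
    NcRnaInteraction,
    SynthConfig,
    assemble_cerna,
    filter_ncrna,
    gen_predictions,
    mirna_consensus,
    pick_circ_isoform,
)

cfg = SynthConfig(seed=1, n_mirnas=12)
sets, truth = gen_predictions(cfg, gene_ids=["APP_like"])
consensus = {"APP_like": mirna_consensus(sets, "APP_like")}
print(f"consensus miRNAs (support >= 4 of 5): {sorted(consensus['APP_like'])}")

mirnas = sorted(consensus["APP_like"])
interactions = [
    NcRnaInteraction("lnc-N1", "lncRNA", m, clip_support=7) for m in mirnas[:3]
] + [NcRnaInteraction("lnc-weak", "lncRNA", mirnas[0], clip_support=3)]
circ_candidates = [
    NcRnaInteraction("circ_A", "circRNA", mirnas[0], 6, samples=10, score=0.5,
                     transcript="TX1"),
    NcRnaInteraction("circ_B", "circRNA", mirnas[0], 6, samples=7, score=0.9,
                     transcript="TX1"),
]
best_circ = pick_circ_isoform(circ_candidates)
circ_hits = [best_circ] + [
    NcRnaInteraction(best_circ.ncrna, "circRNA", m, 6) for m in mirnas[1:3]
]
kept = filter_ncrna(interactions) + circ_hits
net = assemble_cerna(["APP_like"], consensus, kept)
kinds = {}
for _, d in net.nodes(data=True):
    kinds[d["kind"]] = kinds.get(d["kind"], 0) + 1
print(f"network: {net.number_of_nodes()} nodes {kinds}, "
      f"{net.number_of_edges()} edges")
# lnc-weak is dropped by the CLIP gate; circ_A beats circ_B on sample count;
# both surviving ncRNAs enter because each sponges 3 of the 4 consensus
# miRNAs, a strict majority.
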