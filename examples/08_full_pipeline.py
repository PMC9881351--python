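"""Run every stage end-to-end from one synthetic fixture bundle.

``make_fixture`` writes all inputs (two expression cohorts, atlas, PPI edge
list, predictions, survival, genotypes) with a ground-truth sidecar;
``run_pipeline`` consumes them and emits a deterministic report of the
shrinking candidate sets.
"""

import json
import tempfile
from pathlib import Path

from neuromarker.pipeline import _fixture_config, make_fixture, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    bundle = make_fixture(1, Path(tmp) / "bundle")
    report = run_pipeline(_fixture_config(bundle, seed=1))

    dge = report["stages"]["dge"]["datasets"]
    for name, d in dge.items():
        print(f"{name}: {d['n_deg']} DEGs of {d['n_genes']} genes "
              f"({d['n_up']} up / {d['n_down']} down)")
    net = report["stages"]["ppi_network"]
    print(f"PPI: {net['n_nodes']} nodes, {net['n_edges']} edges, "
          f"{len(net['modules'])} modules, {len(net['hubs'])} consensus hubs")
    snp = report["stages"]["snp_assoc"]["snp_1"]
    print(f"SNP: frequency ratio {snp['allele_ratio']} "
          f"(CI {snp['ci95']}), allele p {snp['allele_p']:.4f}")
    truth = json.loads((bundle / "truth.json").read_text())
    print(f"planted allele ratio was {truth['planted_allele_ratio']}")
# Re-running with the same seed reproduces this report byte-for-byte; the
# report mirrors the narrative of candidate sets shrinking stage by stage.
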