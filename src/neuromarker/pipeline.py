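"""End-to-end orchestration of the biomarker-discovery stages.

``make_fixture`` writes a complete synthetic input bundle (with ground-truth
sidecar JSON) that ``run_pipeline`` can consume unedited; ``run_pipeline``
executes the stages in dependency order (differential expression -> tissue
specificity -> PPI network -> enrichment -> ceRNA -> biomarker evaluation,
with SNP association independent) and returns a machine-readable report.
Identical configuration and inputs reproduce the report exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .cerna import assemble_cerna, filter_ncrna, mirna_consensus, pick_circ_isoform
from .dge import (
    DEGFilter,
    apply_deg_filter,
    collapse_duplicate_genes,
    differential_expression,
    intersect_and_merge,
    normalize_log2,
)
from .enrich import GeneSetCollection, gsea_collection, ora
from .evaluate import km_logrank, roc_auc
from .genetics import GenotypeTable, associate
from .network import McodeParams, build_graph, centrality, hub_consensus, mcode_cluster
from .synthetic import (
    SynthConfig,
    default_tissue_mapping,
    gen_expression,
    gen_genotypes,
    gen_ppi,
    gen_predictions,
    gen_survival,
    gen_tissue_atlas,
)
from .tissue import call_all, system_census

__all__ = ["PipelineConfig", "make_fixture", "run_pipeline"]

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths to every stage input plus the screening parameters.

    ``expression`` is a list of (matrix TSV, groups CSV, name) triples; any
    stage whose inputs are ``None`` is skipped, with downstream stages
    consuming whatever upstream results exist.
    """

    expression: list[tuple[str, str, str]] = field(default_factory=list)
    atlas: str | None = None
    tissue_mapping: str | None = None
    ppi_edges: str | None = None
    predictions: str | None = None
    interactions: str | None = None
    survival: str | None = None
    genotypes: str | None = None
    gene_sets: str | None = None

    deg_filter: DEGFilter = field(default_factory=DEGFilter)
    mcode: McodeParams = field(default_factory=McodeParams)
    min_score: float = 0.4
    top_k: int = 14
    min_support: int = 4
    min_clip: int = 5
    majority: float = 0.5
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "deg_filter" in raw:
            raw["deg_filter"] = DEGFilter(**raw["deg_filter"])
        if "mcode" in raw:
            raw["mcode"] = McodeParams(**raw["mcode"])
        if "expression" in raw:
            raw["expression"] = [tuple(t) for t in raw["expression"]]
        return cls(**raw)

    def validate_paths(self) -> None:
        missing = []
        for m, g, _ in self.expression:
            missing += [p for p in (m, g) if not Path(p).exists()]
        for p in (self.atlas, self.tissue_mapping, self.ppi_edges,
                  self.predictions, self.interactions, self.survival,
                  self.genotypes, self.gene_sets):
            if p is not None and not Path(p).exists():
                missing.append(p)
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def make_fixture(seed: int | SynthConfig, outdir: str | Path) -> Path:
    """Write a complete synthetic input bundle plus ground-truth JSON.

    Two expression cohorts are generated (5v4 and 3v3 samples, emulating two
    small test datasets); the PPI graph is planted over the first 150 gene
    IDs so hub calls share the expression namespace; predictions cover those
    same genes. Returns the output directory.
    """
    cfg = seed if isinstance(seed, SynthConfig) else SynthConfig(seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": cfg.seed}

    ds_a, planted_a = gen_expression(cfg)
    cfg_b = dataclasses.replace(cfg, n_case=3, n_control=3, seed=cfg.seed + 1000003)
    ds_b, planted_b = gen_expression(cfg_b)
    io.write_expression_tsv(ds_a, out / "expr_a.tsv", out / "groups_a.csv")
    io.write_expression_tsv(ds_b, out / "expr_b.tsv", out / "groups_b.csv")
    truth["planted_degs"] = {"expr_a": planted_a, "expr_b": planted_b}

    atlas, planted_spec = gen_tissue_atlas(cfg)
    io.write_atlas_tsv(atlas, out / "atlas.tsv")
    mapping = default_tissue_mapping()
    pd.DataFrame(mapping.items(), columns=["tissue", "system"]).to_csv(
        out / "tissue_mapping.csv", index=False
    )
    truth["planted_specific"] = planted_spec

    edges, blocks = gen_ppi(cfg)
    node_map = dict(
        zip(
            [f"P{i:04d}" for i in range(1, cfg.ppi_n_background + 1)],
            cfg.gene_ids[: cfg.ppi_n_background],
        )
    )
    edges = edges.assign(
        node_a=edges["node_a"].map(node_map), node_b=edges["node_b"].map(node_map)
    )
    io.write_edge_list(edges, out / "ppi_edges.tsv")
    truth["planted_modules"] = [[node_map[n] for n in b] for b in blocks]

    pred_genes = cfg.gene_ids[: cfg.ppi_n_background]
    sets, consensus_truth = gen_predictions(cfg, gene_ids=pred_genes)
    io.write_predictions(sets, out / "predictions.tsv")
    truth["consensus_mirnas"] = sorted(next(iter(consensus_truth.values()), set()))

    surv = gen_survival(cfg, ds_a, ds_a.gene_ids[0])
    io.write_survival(surv, out / "survival.csv")

    table, calls = gen_genotypes(cfg)
    io.write_genotype_calls(calls, out / "genotypes.csv")
    truth["planted_allele_ratio"] = cfg.rr_allele
    truth["genotype_counts"] = {g: list(c) for g, c in table.counts.items()}

    io.write_json(truth, out / "truth.json")
    return out


def _fixture_config(outdir: str | Path, seed: int = 0) -> PipelineConfig:
    out = Path(outdir)
    return PipelineConfig(
        expression=[
            (str(out / "expr_a.tsv"), str(out / "groups_a.csv"), "expr_a"),
            (str(out / "expr_b.tsv"), str(out / "groups_b.csv"), "expr_b"),
        ],
        atlas=str(out / "atlas.tsv"),
        tissue_mapping=str(out / "tissue_mapping.csv"),
        ppi_edges=str(out / "ppi_edges.tsv"),
        predictions=str(out / "predictions.tsv"),
        survival=str(out / "survival.csv"),
        genotypes=str(out / "genotypes.csv"),
        seed=seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run report.

    The report records, per stage, the inputs, parameter values and shrinking
    set sizes (DEG counts, specific-gene census, module table, hub sets,
    network sizes, per-gene AUC and log-rank p, association statistics), plus
    the software version and seed.
    """
    config.validate_paths()
    report: dict = {"version": VERSION, "seed": config.seed, "stages": {}}

    # --- differential expression ------------------------------------------
    datasets, deg_sets = [], []
    if config.expression:
        stage: dict = {"datasets": {}}
        for matrix, groups, name in config.expression:
            raw = pd.read_csv(matrix, sep="\t", index_col=0)
            raw = collapse_duplicate_genes(raw)
            gdf = pd.read_csv(groups)
            ds = normalize_log2(raw, pd.Series(dict(zip(gdf["sample"], gdf["group"]))),
                                name=name)
            records = differential_expression(ds)
            degs = apply_deg_filter(records, config.deg_filter)
            datasets.append(ds)
            deg_sets.append(degs)
            stage["datasets"][name] = {
                "n_genes": len(ds.gene_ids),
                "n_samples": len(ds.sample_ids),
                "log_transformed": ds.log_transformed,
                "n_deg": len(degs.genes),
                "n_up": len(degs.up),
                "n_down": len(degs.down),
            }
        if len(deg_sets) >= 2:
            intersection, merged = intersect_and_merge(deg_sets, datasets)
            stage["intersection"] = sorted(intersection)
            stage["union_size"] = len(set.union(*(d.genes for d in deg_sets)))
            stage["merged_shape"] = list(merged.values.shape)
        else:
            merged = datasets[0]
            stage["intersection"] = sorted(deg_sets[0].genes)
        report["stages"]["dge"] = stage
        deg_union = set.union(*(d.genes for d in deg_sets))
    else:
        merged, deg_union = None, set()

    # --- tissue specificity ------------------------------------------------
    nervous: set = set()
    if config.atlas:
        mapping = (
            io.read_tissue_mapping(config.tissue_mapping)
            if config.tissue_mapping
            else default_tissue_mapping()
        )
        atlas = io.read_atlas_tsv(config.atlas, mapping)
        genes = sorted(deg_union & set(atlas.gene_ids)) or None
        calls = call_all(atlas, genes)
        census = system_census(calls)
        nervous = {
            g
            for row in census.itertuples()
            if row.system == "nervous"
            for g in row.genes
        }
        report["stages"]["tissue_specificity"] = {
            "n_called": len(calls),
            "n_specific": int(calls["specific"].sum()),
            "census": census.drop(columns=["genes"]).to_dict("records"),
            "nervous_genes": sorted(nervous),
        }

    # --- PPI network -------------------------------------------------------
    hubs, system_hubs = set(), set()
    if config.ppi_edges:
        edges = io.read_edge_list(config.ppi_edges)
        graph = build_graph(edges, min_score=config.min_score)
        modules = mcode_cluster(graph, config.mcode)
        rankings = [
            centrality(graph, m, k=config.top_k)
            for m in ("MCC", "Degree", "DMNC", "MNC", "ClusteringCoefficient")
        ]
        hubs, system_hubs = hub_consensus(rankings, nervous)
        report["stages"]["ppi_network"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "modules": [
                {"n_nodes": m.n_nodes, "n_edges": m.n_edges,
                 "score": round(m.score, 3), "members": sorted(m.members)}
                for m in modules
            ],
            "hubs": sorted(hubs),
            "system_hubs": sorted(system_hubs),
        }

    # --- enrichment --------------------------------------------------------
    if config.gene_sets and merged is not None and deg_union:
        collection = GeneSetCollection(io.read_gmt(config.gene_sets))
        universe = set(merged.gene_ids) | deg_union
        ora_res = ora(deg_union & universe, universe, collection)
        records = differential_expression(datasets[0])
        ranking = pd.Series(records["t"].to_numpy(), index=records["gene"])
        gsea_res = gsea_collection(
            ranking, collection, weight=config.gsea_weight,
            n_perm=config.gsea_n_perm, seed=config.seed,
        )
        report["stages"]["enrichment"] = {
            "ora": ora_res.drop(columns=[], errors="ignore").to_dict("records"),
            "gsea": gsea_res.drop(columns=["leading_edge"]).to_dict("records"),
        }

    # --- ceRNA -------------------------------------------------------------
    if config.predictions:
        focus = sorted(system_hubs or hubs) or sorted(deg_union)[:5]
        sets = io.read_predictions(config.predictions)
        consensus = {}
        for gene in focus:
            consensus[gene] = mirna_consensus(sets, gene, config.min_support)
        interactions = []
        if config.interactions:
            kept = filter_ncrna(io.read_interactions(config.interactions),
                                config.min_clip)
            by_tx: dict[str, list] = {}
            for it in kept:
                if it.kind == "circRNA" and it.transcript:
                    by_tx.setdefault((it.transcript, it.mirna), []).append(it)
                else:
                    interactions.append(it)
            for cands in by_tx.values():
                interactions.append(pick_circ_isoform(cands))
        net = assemble_cerna(focus, consensus, interactions, config.majority)
        kinds = pd.Series(
            [d["kind"] for _, d in net.nodes(data=True)]
        ).value_counts().to_dict()
        report["stages"]["cerna"] = {
            "genes": focus,
            "consensus_sizes": {g: len(m) for g, m in consensus.items()},
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "nodes_by_kind": kinds,
        }

    # --- biomarker evaluation ---------------------------------------------
    if merged is not None and (hubs or deg_union):
        stage = {}
        surv = io.read_survival(config.survival) if config.survival else None
        eval_genes = sorted(hubs or deg_union)[:10]
        first = datasets[0]
        for gene in eval_genes:
            entry = {}
            if gene in merged.values.index:
                roc = roc_auc(
                    merged.values.loc[gene], merged.groups[merged.sample_ids]
                )
                entry["auc"] = round(roc.auc, 4)
            if surv is not None and gene in first.values.index:
                expr = first.values.loc[gene, first.samples_in("case")]
                try:
                    km = km_logrank(expr, surv)
                    entry["logrank_chi2"] = round(km.chi2, 4)
                    entry["logrank_p"] = km.p
                except ValueError as exc:
                    entry["logrank_error"] = str(exc)
            if entry:
                stage[gene] = entry
        report["stages"]["biomarker_eval"] = stage

    # --- SNP association (independent) ------------------------------------
    if config.genotypes:
        calls = io.read_genotype_calls(config.genotypes)
        stage = {}
        for snp in sorted(calls["snp"].unique()):
            table = GenotypeTable.from_subjects(calls, snp)
            res = associate(table)
            stage[snp] = {
                "allele_ratio": round(res.allele_ratio, 3),
                "ci95": [round(v, 3) for v in res.ci95] if res.ci95 else None,
                "allele_p": res.allele_p,
                "major_ratio": round(res.major_ratio, 3),
                "dominant_fisher_p": res.dominant_p,
                "frequencies_pct": res.percent_strings,
                "degenerate": res.degenerate,
            }
        report["stages"]["snp_assoc"] = stage

    return report


def write_report(report: dict, json_path: str | Path,
                 md_path: str | Path | None = None) -> None:
    """Serialize the run report as JSON and an optional Markdown summary."""
    io.write_json(report, json_path)
    if md_path is None:
        return
    lines = [f"# Pipeline report (seed {report['seed']})", ""]
    for stage, body in report["stages"].items():
        lines.append(f"## {stage}")
        lines.append("```json")
        import json as _json

        lines.append(_json.dumps(body, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    Path(md_path).write_text("\n".join(lines))
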