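"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure its downstream stage
assumes: log2-scale case/control expression with planted differential genes,
a tissue atlas with planted nervous-system-specific genes, a background PPI
graph with planted dense modules, target-prediction sources with a controlled
cross-source overlap profile, exponential survival with an expression-linked
hazard, and Hardy-Weinberg genotypes with a planted case/control
minor-allele-frequency ratio.

All randomness flows from the single ``SynthConfig.seed`` through independent
named substreams, so adding one generator never perturbs another's output and
identical configs give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .dge import ExpressionDataset
from .genetics import GenotypeTable
from .tissue import TissueAtlas

__all__ = ["SynthConfig", "ConfigError", "default_tissue_mapping",
           "gen_expression", "gen_tissue_atlas", "gen_ppi",
           "gen_predictions", "gen_survival", "gen_genotypes"]

# fixed substream ids: appending new generators must not renumber old ones
_STREAMS = {
    "expression": 0,
    "atlas": 1,
    "ppi": 2,
    "predictions": 3,
    "survival": 4,
    "genotypes": 5,
}


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


def default_tissue_mapping() -> dict[str, str]:
    """Tissue -> organ-system map shipped with the package (12 tissues over
    the nervous / haematologic-immune / digestive / respiratory / circulatory /
    placenta / endocrine / genital systems)."""
    path = resources.files("neuromarker.data") / "tissue_systems.csv"
    df = pd.read_csv(path)
    return dict(zip(df["tissue"], df["system"]))


@dataclass
class SynthConfig:
    """One stated world for all generators.

    Expression defaults mirror a two-small-cohort microarray design (5 cases
    vs 4 controls), planted effect 2.0 log2 units over noise SD 0.5; the PPI
    background is Erdos-Renyi n=150, p=0.02 with planted dense blocks of
    sizes 14/15/9 at within-block edge probability 0.9; genotypes use a
    30+30 case-control design at control minor-allele frequency 0.083 with a
    planted case/control frequency ratio of 3.0.
    """

    # expression
    n_genes: int = 1000
    n_case: int = 5
    n_control: int = 4
    n_de: int = 50
    de_log2fc: float = 2.0
    noise_sd: float = 0.5
    # tissue atlas
    n_tissues: int = 12
    n_specific: int = 20
    specificity_fold: float = 50.0
    # PPI
    ppi_n_background: int = 150
    ppi_p_background: float = 0.02
    module_sizes: tuple[int, ...] = (14, 15, 9)
    module_p: float = 0.9
    # predictions
    n_sources: int = 5
    n_mirnas: int = 30
    overlap_profile: tuple[int, ...] | None = None
    # survival
    hazard_beta: float = 1.5
    censor_rate: float = 0.2
    baseline_median_months: float = 36.0
    # genotypes
    n_snp_case: int = 30
    n_snp_control: int = 30
    control_maf: float = 0.083
    rr_allele: float = 3.0
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_genes": self.n_genes, "n_case": self.n_case,
            "n_control": self.n_control, "n_tissues": self.n_tissues,
            "ppi_n_background": self.ppi_n_background,
            "n_sources": self.n_sources, "n_mirnas": self.n_mirnas,
            "n_snp_case": self.n_snp_case, "n_snp_control": self.n_snp_control,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.n_de < 0 or self.n_de > self.n_genes:
            raise ConfigError("need 0 <= n_de <= n_genes")
        if self.n_specific < 0 or self.n_specific > self.n_genes:
            raise ConfigError("need 0 <= n_specific <= n_genes")
        if self.n_specific > 0 and self.specificity_fold <= 10:
            raise ConfigError(
                "specificity_fold must exceed 10 to plant genes that pass the "
                "10x-median rule"
            )
        if any(m > self.ppi_n_background for m in self.module_sizes):
            raise ConfigError("module sizes must not exceed ppi_n_background")
        if sum(self.module_sizes) > self.ppi_n_background:
            raise ConfigError("planted modules must fit disjointly in the graph")
        if self.module_sizes and self.module_p <= self.ppi_p_background:
            raise ConfigError("module_p must exceed ppi_p_background")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must be in [0, 1)")
        if self.rr_allele < 0 or self.rr_allele * self.control_maf > 1:
            raise ConfigError("rr_allele x control_maf must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"mir-{i:03d}" for i in range(1, self.n_mirnas + 1)]


def gen_expression(cfg: SynthConfig) -> tuple[ExpressionDataset, list[str]]:
    """Log2-scale case/control matrix with ``n_de`` planted DEGs.

    Per-gene baselines are uniform on [4, 12] log2 units; i.i.d. Gaussian
    noise with SD ``noise_sd`` is added per entry; planted genes have their
    case mean shifted by ``de_log2fc``. Returns the dataset and the planted
    gene IDs (ground truth).
    """
    rng = cfg.rng("expression")
    genes = cfg.gene_ids
    samples = [f"case_{i+1}" for i in range(cfg.n_case)] + [
        f"ctrl_{i+1}" for i in range(cfg.n_control)
    ]
    baseline = rng.uniform(4, 12, size=cfg.n_genes)
    values = baseline[:, None] + rng.normal(
        0, cfg.noise_sd, size=(cfg.n_genes, len(samples))
    )
    planted_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_de, replace=False))
    values[planted_idx, : cfg.n_case] += cfg.de_log2fc
    groups = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control, index=samples
    )
    ds = ExpressionDataset(
        pd.DataFrame(values, index=genes, columns=samples), groups, name="synthetic"
    )
    return ds, [genes[i] for i in planted_idx]


def gen_tissue_atlas(
    cfg: SynthConfig, mapping: dict[str, str] | None = None
) -> tuple[TissueAtlas, list[str]]:
    """Linear-scale atlas with ``n_specific`` planted nervous-system genes.

    Background profiles are near-uniform (1 +/- 20%), which fails the
    10x-median rule by construction; planted genes get value
    ``specificity_fold`` in one nervous-system tissue over that background,
    passing both rules. Returns the atlas and planted gene IDs.
    """
    mapping = mapping or default_tissue_mapping()
    tissues = list(mapping)[: cfg.n_tissues]
    if len(tissues) < 3:
        raise ConfigError("need at least 3 mapped tissues")
    rng = cfg.rng("atlas")
    genes = cfg.gene_ids
    values = rng.uniform(0.8, 1.2, size=(cfg.n_genes, len(tissues)))
    nervous = [i for i, t in enumerate(tissues) if mapping[t] == "nervous"]
    if cfg.n_specific > 0 and not nervous:
        raise ConfigError("mapping has no nervous-system tissue to plant into")
    planted_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_specific, replace=False))
    for i in planted_idx:
        values[i, rng.choice(nervous)] = cfg.specificity_fold
    atlas = TissueAtlas(
        pd.DataFrame(values, index=genes, columns=tissues),
        {t: mapping[t] for t in tissues},
    )
    return atlas, [genes[i] for i in planted_idx]


def gen_ppi(cfg: SynthConfig) -> tuple[pd.DataFrame, list[list[str]]]:
    """Erdos-Renyi background with planted denser blocks, as an edge list.

    Nodes are ``P0001..``; disjoint blocks of ``module_sizes`` nodes get
    within-block edge probability ``module_p`` against background
    ``ppi_p_background``. Block edges carry combined scores uniform on
    [0.7, 1.0], background edges uniform on [0.15, 0.95], so the standard
    score > 0.4 filter keeps planted structure intact. Returns the edge list
    (``node_a, node_b, combined_score``) and the planted block memberships.
    """
    rng = cfg.rng("ppi")
    n = cfg.ppi_n_background
    nodes = [f"P{i:04d}" for i in range(1, n + 1)]
    perm = rng.permutation(n)
    blocks, start = [], 0
    for size in cfg.module_sizes:
        blocks.append(sorted(perm[start : start + size]))
        start += size
    in_block = {}
    for b, members in enumerate(blocks):
        for i in members:
            in_block[i] = b
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            same = in_block.get(i) is not None and in_block.get(i) == in_block.get(j)
            p = cfg.module_p if same else cfg.ppi_p_background
            if rng.random() < p:
                score = rng.uniform(0.7, 1.0) if same else rng.uniform(0.15, 0.95)
                rows.append((nodes[i], nodes[j], round(float(score), 4)))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])
    membership = [[nodes[i] for i in b] for b in blocks]
    return edges, membership


def gen_predictions(
    cfg: SynthConfig,
    gene_ids: list[str] | None = None,
    mirna_ids: list[str] | None = None,
) -> tuple[list, dict[str, set[str]]]:
    """Per-source (mirna, gene) prediction sets with controlled overlap.

    Each miRNA is predicted by exactly ``overlap_profile[i]`` of the
    ``n_sources`` sources (default profile cycles 5,4,3,2,1,0), identically
    for every gene, with the supporting sources drawn at random. Returns the
    prediction sets and the ground-truth consensus (support >= 4) per gene.
    """
    from .cerna import TargetPredictionSet, normalize_mirna

    rng = cfg.rng("predictions")
    genes = list(gene_ids) if gene_ids is not None else cfg.gene_ids[:5]
    mirnas = [normalize_mirna(m) for m in (mirna_ids or cfg.mirna_ids)]
    profile = cfg.overlap_profile or tuple(
        (5, 4, 3, 2, 1, 0)[i % 6] for i in range(len(mirnas))
    )
    if len(profile) != len(mirnas):
        raise ConfigError("overlap_profile length must match the miRNA list")
    if any(s < 0 or s > cfg.n_sources for s in profile):
        raise ConfigError("overlap supports must lie in [0, n_sources]")
    sources = [f"src_{chr(65 + i)}" for i in range(cfg.n_sources)]
    pairs: dict[str, set] = {s: set() for s in sources}
    for mirna, support in zip(mirnas, profile):
        chosen = rng.choice(cfg.n_sources, size=support, replace=False)
        for s in chosen:
            for gene in genes:
                pairs[sources[s]].add((mirna, gene))
    truth = {
        g: {m for m, sup in zip(mirnas, profile) if sup >= 4} for g in genes
    }
    return [TargetPredictionSet(s, pairs[s]) for s in sources], truth


def gen_survival(
    cfg: SynthConfig, dataset: ExpressionDataset, gene: str
) -> pd.DataFrame:
    """Exponential survival for case samples with expression-linked hazard.

    Event times are exponential with log-hazard ``hazard_beta`` x the
    standardized expression of ``gene`` (baseline median survival
    ``baseline_median_months``); a ``censor_rate`` fraction of subjects are
    censored uniformly before their event time. Returns columns
    ``sample, time, event``.
    """
    if gene not in dataset.values.index:
        raise KeyError(f"gene {gene!r} not in dataset")
    rng = cfg.rng("survival")
    samples = dataset.samples_in("case")
    expr = dataset.values.loc[gene, samples].to_numpy(dtype=float)
    sd = expr.std()
    z = (expr - expr.mean()) / sd if sd > 0 else np.zeros_like(expr)
    scale = cfg.baseline_median_months / np.log(2)
    times = rng.exponential(scale * np.exp(-cfg.hazard_beta * z))
    censored = rng.random(len(samples)) < cfg.censor_rate
    observed = np.where(censored, rng.uniform(0, times), times)
    observed = np.maximum(observed, 1e-6)
    return pd.DataFrame(
        {
            "sample": samples,
            "time": observed,
            "event": (~censored).astype(int),
        }
    )


def gen_genotypes(
    cfg: SynthConfig, snp: str = "snp_1", minor: str = "G", major: str = "C"
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Hardy-Weinberg genotypes at the planted allele-frequency ratio.

    Controls draw minor-allele dosage Binomial(2, control_maf); cases use
    MAF = rr_allele x control_maf. Returns the aggregated GenotypeTable and
    the per-subject calls (``subject, group, snp, genotype``).
    """
    rng = cfg.rng("genotypes")
    rows = []
    counts = {}
    for group, n, maf in (
        ("case", cfg.n_snp_case, cfg.rr_allele * cfg.control_maf),
        ("control", cfg.n_snp_control, cfg.control_maf),
    ):
        dosage = rng.binomial(2, maf, size=n)
        counts[group] = (
            int((dosage == 2).sum()),
            int((dosage == 1).sum()),
            int((dosage == 0).sum()),
        )
        for i, d in enumerate(dosage):
            gt = {2: minor + minor, 1: minor + major, 0: major + major}[int(d)]
            rows.append((f"{group}_{i+1:03d}", group, snp, gt))
    table = GenotypeTable(snp=snp, minor=minor, major=major, counts=counts)
    calls = pd.DataFrame(rows, columns=["subject", "group", "snp", "genotype"])
    return table, calls
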