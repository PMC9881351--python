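"""Competing-endogenous-RNA (ceRNA) network assembly.

Target miRNAs of hub genes are called by consensus across prediction sources
(kept when found in at least 4 of 5 sources by default); lncRNA/circRNA-miRNA
interactions are filtered by CLIP support (>= 5); multiple circRNA isoforms of
one transcript collapse to the best-supported one; the final network is
tripartite: mRNA-miRNA, miRNA-lncRNA and miRNA-circRNA edges only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = [
    "TargetPredictionSet",
    "NcRnaInteraction",
    "mirna_consensus",
    "filter_ncrna",
    "pick_circ_isoform",
    "assemble_cerna",
]

NCRNA_KINDS = {"lncRNA", "circRNA"}


@dataclass
class TargetPredictionSet:
    """One prediction source's (mirna, gene) pairs. Pairs are unique within
    a source; miRNA IDs are matched case-insensitively with -3p/-5p suffixes
    kept significant."""

    source: str
    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = {(normalize_mirna(m), g) for m, g in self.pairs}


def normalize_mirna(mirna: str) -> str:
    """Lowercase the species/miR prefix, keep -3p/-5p arm suffixes distinct."""
    return mirna.strip().lower()


@dataclass
class NcRnaInteraction:
    ncrna: str
    kind: str  # lncRNA | circRNA
    mirna: str
    clip_support: int
    samples: int = 0
    score: float = 0.0
    transcript: str = ""  # parent transcript for circRNA isoform collapse

    def __post_init__(self) -> None:
        if self.kind not in NCRNA_KINDS:
            raise ValueError(f"kind must be one of {sorted(NCRNA_KINDS)}")
        if self.clip_support < 0:
            raise ValueError("clip_support must be >= 0")
        self.mirna = normalize_mirna(self.mirna)


def mirna_consensus(
    prediction_sets: list[TargetPredictionSet], gene: str, min_support: int = 4
) -> set[str]:
    """miRNAs predicted to target ``gene`` by at least ``min_support``
    distinct sources."""
    sources = {ps.source for ps in prediction_sets}
    if len(sources) < min_support:
        raise ValueError(
            f"{len(sources)} distinct sources supplied; need >= {min_support}"
        )
    support: dict[str, set[str]] = {}
    for ps in prediction_sets:
        for mirna, g in ps.pairs:
            if g == gene:
                support.setdefault(mirna, set()).add(ps.source)
    return {m for m, srcs in support.items() if len(srcs) >= min_support}


def filter_ncrna(
    interactions: list[NcRnaInteraction], min_clip: int = 5
) -> list[NcRnaInteraction]:
    """Keep interactions with CLIP support >= min_clip (inclusive)."""
    return [i for i in interactions if i.clip_support >= min_clip]


def pick_circ_isoform(candidates: list[NcRnaInteraction]) -> NcRnaInteraction:
    """Pick one circRNA isoform per transcript: most samples, then highest
    score, then lexicographically smallest ID (deterministic)."""
    if not candidates:
        raise ValueError("no isoform candidates supplied")
    parents = {c.transcript for c in candidates}
    if len(parents) > 1:
        raise ValueError(f"candidates span multiple transcripts: {sorted(parents)}")
    return sorted(candidates, key=lambda c: (-c.samples, -c.score, c.ncrna))[0]


def assemble_cerna(
    hub_genes: list[str],
    consensus_mirnas: dict[str, set[str]],
    ncrna_interactions: list[NcRnaInteraction] | None = None,
    majority: float = 0.5,
) -> nx.Graph:
    """Assemble the tripartite mRNA-miRNA-ncRNA network.

    Every (gene, consensus miRNA) pair becomes an mRNA-miRNA edge. An ncRNA
    is attached for a gene only when it interacts with a strict majority
    (> ``majority`` fraction) of that gene's consensus miRNAs; its edges go to
    the consensus miRNAs it hits. Node attribute ``kind`` is one of
    mRNA/miRNA/lncRNA/circRNA; edge attribute ``edge_type`` records the pair
    type. The tripartite constraint is asserted on every build.
    """
    g = nx.Graph()
    for gene in hub_genes:
        g.add_node(gene, kind="mRNA")
        for mirna in sorted(consensus_mirnas.get(gene, set())):
            g.add_node(mirna, kind="miRNA")
            g.add_edge(gene, mirna, edge_type="mRNA-miRNA")

    by_ncrna: dict[str, list[NcRnaInteraction]] = {}
    for it in ncrna_interactions or []:
        by_ncrna.setdefault(it.ncrna, []).append(it)
    for ncrna in sorted(by_ncrna):
        its = by_ncrna[ncrna]
        kind = its[0].kind
        hit_mirnas = {it.mirna for it in its}
        for gene in hub_genes:
            consensus = consensus_mirnas.get(gene, set())
            if not consensus:
                continue
            hits = consensus & hit_mirnas
            if len(hits) > majority * len(consensus):
                g.add_node(ncrna, kind=kind)
                for mirna in sorted(hits):
                    g.add_edge(ncrna, mirna, edge_type=f"miRNA-{kind}")

    for a, b in g.edges:
        kinds = {g.nodes[a]["kind"], g.nodes[b]["kind"]}
        assert "miRNA" in kinds and len(kinds) == 2, (
            f"tripartite constraint violated by edge {a}-{b} ({kinds})"
        )
    return g
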