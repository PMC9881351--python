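"""Gene-set enrichment: hypergeometric over-representation analysis (ORA)
and pre-ranked enrichment with a weighted running-sum statistic and a
gene-permutation null.

Collections are user-supplied (GMT); sets are intersected with the analysis
universe and filtered to [min_size, max_size] before testing. A set is
flagged significant when q < 0.05 and (for pre-ranked) permutation
FDR < 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "ora",
    "gsea_preranked",
    "gsea_collection",
]

Q_SIGNIFICANT = 0.05
FDR_SIGNIFICANT = 0.25


@dataclass
class GeneSetCollection:
    """Named gene sets with size bounds applied after intersection with a
    universe (defaults 5 and 5000)."""

    sets: dict[str, set[str]]
    min_size: int = 5
    max_size: int = 5000

    def filtered(self, universe: set[str]) -> tuple[dict[str, set[str]], list[str]]:
        """Intersect with ``universe`` and apply the size bounds; returns the
        kept sets and the names skipped for size."""
        kept, skipped = {}, []
        for name, genes in self.sets.items():
            g = set(genes) & universe
            if self.min_size <= len(g) <= self.max_size:
                kept[name] = g
            else:
                skipped.append(name)
        return kept, skipped


@dataclass
class EnrichmentResult:
    set_name: str
    statistic: float  # hypergeometric p (ORA) or enrichment score (pre-ranked)
    p: float
    q: float = float("nan")
    nes: float = float("nan")
    fdr: float = float("nan")
    overlap: int = 0
    set_size: int = 0
    leading_edge: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        fdr_ok = True if np.isnan(self.fdr) else self.fdr < FDR_SIGNIFICANT
        return self.q < Q_SIGNIFICANT and fdr_ok


def ora(
    genes: set[str], universe: set[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``genes`` in each set.

    ``genes`` must be a subset of ``universe``; p is the upper tail
    P(overlap >= observed); q is Benjamini-Hochberg across tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(genes)
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    sets, _skipped = collection.filtered(universe)
    M, n = len(universe), len(genes)
    rows = []
    for name in sorted(sets):
        members = sets[name]
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n))
        rows.append(
            {"set_name": name, "overlap": k, "set_size": len(members), "p": p}
        )
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < Q_SIGNIFICANT
    else:
        out["q"] = []
        out["significant"] = []
    return out.sort_values(["p", "set_name"]).reset_index(drop=True)


def _running_es(
    hit: np.ndarray, weight_abs: np.ndarray, weight: float
) -> tuple[float, int]:
    """Signed enrichment score and peak index of the weighted running sum.

    ``hit`` is a boolean array over the ranking (descending scores);
    hits advance by |score|^weight normalized to 1, misses by 1/(N - Nh).
    """
    n = hit.size
    nh = int(hit.sum())
    w = weight_abs**weight if weight != 0 else np.ones(n)
    hit_w = np.where(hit, w, 0.0)
    nr = hit_w.sum()
    if nr == 0:  # all hit scores exactly zero at weight > 0
        hit_w = hit.astype(float)
        nr = float(nh)
    step = hit_w / nr - (~hit) / float(n - nh)
    running = np.cumsum(step)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def gsea_preranked(
    ranked: pd.Series | dict[str, float],
    gene_set: set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Pre-ranked enrichment of one gene set against a gene -> score ranking.

    The statistic is the extreme deviation of the weighted running sum over
    genes sorted by decreasing score (ties broken by gene ID). The null is
    gene-label permutation: set membership reassigned to random positions,
    ``n_perm`` times, under a fixed ``seed``. NES divides ES by the mean
    |null ES| of matching sign; the permutation p and FDR are one-sided on
    that matching-sign null.
    """
    s = pd.Series(ranked, dtype=float)
    if s.index.duplicated().any():
        raise ValueError("ranked list has duplicate genes")
    order = s.sort_values(ascending=False, kind="mergesort")
    # deterministic tie-break on gene ID within equal scores
    order = order.iloc[
        np.lexsort((order.index.astype(str), -order.to_numpy()))
    ]
    genes = order.index.to_numpy()
    scores = order.to_numpy()
    hit = np.isin(genes, list(gene_set))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == genes.size:
        raise ValueError("gene set covers the whole ranked list; no misses")
    weight_abs = np.abs(scores)
    es, peak = _running_es(hit, weight_abs, weight)
    leading = (
        [g for g in genes[: peak + 1] if g in gene_set]
        if es >= 0
        else [g for g in genes[peak:] if g in gene_set]
    )

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_hit = np.zeros(genes.size, dtype=bool)
        perm_hit[rng.choice(genes.size, size=nh, replace=False)] = True
        null[i], _ = _running_es(perm_hit, weight_abs, weight)
    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        p = 1.0 / n_perm
        nes = float("nan")
        fdr = p
    else:
        tail = np.abs(null[same_sign]) >= abs(es)
        p = float(tail.mean())
        mean_null = float(np.abs(null[same_sign]).mean())
        nes = es / mean_null if mean_null > 0 else float("nan")
        fdr = p  # single-set FDR reduces to the normalized tail fraction
    return EnrichmentResult(
        set_name="",
        statistic=es,
        p=p,
        nes=nes,
        fdr=min(fdr, 1.0),
        overlap=nh,
        set_size=len(gene_set),
        leading_edge=list(leading),
    )


def gsea_collection(
    ranked: pd.Series | dict[str, float],
    collection: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked enrichment over a whole collection with BH q across sets."""
    s = pd.Series(ranked, dtype=float)
    sets, _skipped = collection.filtered(set(s.index))
    rows = []
    for i, name in enumerate(sorted(sets)):
        res = gsea_preranked(s, sets[name], weight=weight, n_perm=n_perm,
                             seed=seed + i)
        rows.append(
            {
                "set_name": name,
                "es": res.statistic,
                "nes": res.nes,
                "p": res.p,
                "fdr": res.fdr,
                "overlap": res.overlap,
                "leading_edge": res.leading_edge,
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "es", "nes", "p", "fdr", "overlap",
                       "leading_edge"]
    )
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = (out["q"] < Q_SIGNIFICANT) & (out["fdr"] < FDR_SIGNIFICANT)
    else:
        out["q"] = []
        out["significant"] = []
    return out.sort_values(["p", "set_name"]).reset_index(drop=True)
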