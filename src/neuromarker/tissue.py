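"""Tissue/organ-system specificity screening of candidate genes.

A gene is called tissue-specific when, across an expression atlas of tissues,
(1) its top tissue exceeds 10x the median of its profile and (2) the
second-highest tissue is no more than one-third of the top. Tissues tied at
the top must all map to one organ system; ties across systems are called
not-specific and flagged. Specific genes are then tabulated per organ system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TissueAtlas", "SpecificityCall", "call_specificity", "call_all",
           "system_census"]


@dataclass
class TissueAtlas:
    """Genes x tissues linear-scale expression with a tissue -> organ-system map."""

    values: pd.DataFrame
    system_of: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("atlas values must be non-negative")
        unmapped = [t for t in self.values.columns if t not in self.system_of]
        if unmapped:
            raise ValueError(f"tissues without an organ-system mapping: {unmapped}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SpecificityCall:
    gene: str
    specific: bool
    system: str | None
    top_tissue: str
    top_value: float
    second_value: float
    median_value: float
    tied_across_systems: bool = False


def call_specificity(atlas: TissueAtlas, gene: str) -> SpecificityCall:
    """Evaluate both specificity rules for one gene.

    Rule 1: max > 10 x median of the gene's profile (for an all-flat zero
    median this degenerates to max > 0, so all-zero profiles are never
    specific). Rule 2: second-highest value <= max / 3. A tie at the top
    spanning more than one organ system is flagged and called not-specific.
    """
    if gene not in atlas.values.index:
        raise KeyError(f"gene {gene!r} not in atlas")
    if atlas.values.shape[1] < 3:
        raise ValueError("need at least 3 tissues to call specificity")
    profile = atlas.values.loc[gene].astype(float)
    med = float(profile.median())
    order = profile.sort_values(ascending=False, kind="mergesort")
    top_tissue = str(order.index[0])
    top = float(order.iloc[0])
    second = float(order.iloc[1])
    tied_top = [t for t, v in profile.items() if v == top]
    systems = {atlas.system_of[t] for t in tied_top}
    tied_across = len(systems) > 1
    rule1 = top > 10.0 * med
    rule2 = second <= top / 3.0
    specific = rule1 and rule2 and not tied_across
    return SpecificityCall(
        gene=gene,
        specific=specific,
        system=atlas.system_of[top_tissue] if specific else None,
        top_tissue=top_tissue,
        top_value=top,
        second_value=second,
        median_value=med,
        tied_across_systems=tied_across,
    )


def call_all(atlas: TissueAtlas, genes: list[str] | None = None) -> pd.DataFrame:
    """Specificity calls for every gene (or a subset) as one DataFrame."""
    genes = list(genes) if genes is not None else atlas.gene_ids
    calls = [call_specificity(atlas, g) for g in genes]
    return pd.DataFrame([vars(c) for c in calls])


def system_census(calls: pd.DataFrame) -> pd.DataFrame:
    """Count specific genes per organ system, with fractions of the specific set.

    Returns columns ``system, genes, count, fraction`` sorted by count
    descending; fractions sum to 1 over the specific genes.
    """
    spec = calls[calls["specific"]]
    if len(spec) == 0:
        return pd.DataFrame(columns=["system", "genes", "count", "fraction"])
    rows = []
    total = len(spec)
    for system, sub in spec.groupby("system"):
        genes = sorted(sub["gene"])
        rows.append(
            {
                "system": system,
                "genes": genes,
                "count": len(genes),
                "fraction": len(genes) / total,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["count", "system"], ascending=[False, True])
        .reset_index(drop=True)
    )
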