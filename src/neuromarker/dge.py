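"""Differential expression between case and control expression profiles.

The screening stage of the pipeline: per-gene two-sample t statistics on
log2-scale matrices, Benjamini-Hochberg adjustment, and the fold-change /
adjusted-p filter (|log2FC| > 1.5, p_adj <= 0.05 by default). Multiple
datasets are screened independently and their DEG sets intersected and
merged into one matrix for the network stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionDataset",
    "DEGFilter",
    "DEGSet",
    "collapse_duplicate_genes",
    "normalize_log2",
    "differential_expression",
    "apply_deg_filter",
    "intersect_and_merge",
]

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """A genes x samples log2 expression matrix with case/control labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample, log2 scale.
    groups
        Series mapping every sample ID to ``"case"`` or ``"control"``.
    name
        Dataset label, retained as sample provenance when matrices are merged.
    """

    values: pd.DataFrame
    groups: pd.Series
    name: str = ""
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control', got {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.values.index.duplicated().any():
            raise ValueError(
                "duplicate gene IDs; collapse with collapse_duplicate_genes() first"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene IDs (multiple probes) to the highest-mean probe."""
    if not values.index.duplicated().any():
        return values
    order = values.mean(axis=1).to_numpy()
    keep = (
        pd.DataFrame({"gene": values.index, "mean": order, "pos": range(len(values))})
        .sort_values(["gene", "mean", "pos"], ascending=[True, False, True])
        .drop_duplicates("gene")["pos"]
        .sort_values()
    )
    return values.iloc[list(keep)]


def normalize_log2(
    values: pd.DataFrame, groups: pd.Series, name: str = ""
) -> ExpressionDataset:
    """Guard against linear-scale input: log2(x+1) when max value > 50.

    Matrices already on log2 scale (max <= 50) pass through unchanged; the
    branch taken is recorded on the returned dataset.
    """
    arr = values.to_numpy(dtype=float)
    transformed = False
    if np.nanmax(arr) > 50:
        if (arr < 0).any():
            raise ValueError("negative values on linear-scale input")
        values = np.log2(values + 1.0)
        transformed = True
    return ExpressionDataset(values, groups, name=name, log_transformed=transformed)


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene pooled variances.

    Fits a scaled inverse-chi-square prior (prior variance s2_0, prior df d0)
    to the observed variances by the method of moments on log variances and
    returns the posterior variances (d0*s2_0 + df*s2)/(d0 + df) with the
    total degrees of freedom df + d0 (inf when the variances are consistent
    with a single common value).
    """
    from scipy.special import digamma, polygamma

    ok = s2 > 0
    if ok.sum() < 2:
        return s2, df
    z = np.log(s2[ok])
    e = z - digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) * (len(e) - 1) / len(e) - polygamma(1, df / 2)
    if e_var <= 0:
        s2_0 = float(np.exp(e_mean))
        return np.full_like(s2, s2_0), float("inf")
    # invert trigamma(d0/2) = e_var by Newton iteration
    y = 0.5 + 1.0 / e_var
    for _ in range(50):
        tri = polygamma(1, y)
        delta = tri * (1 - tri / e_var) / polygamma(2, y)
        y += delta
        if abs(delta) < 1e-10:
            break
    d0 = 2.0 * float(y)
    s2_0 = float(np.exp(e_mean + digamma(d0 / 2) - np.log(d0 / 2)))
    return (d0 * s2_0 + df * s2) / (d0 + df), df + d0


def differential_expression(
    ds: ExpressionDataset, shrinkage: str | None = "moderated",
) -> pd.DataFrame:
    """Per-gene two-sample t-test, case vs control, with variance shrinkage.

    Returns a DataFrame with columns ``gene, log2fc, t, p, p_adj, regulation``
    sorted by adjusted then raw p (ties broken by gene ID). ``log2fc`` is
    mean(case) - mean(control) on the log2 scale; adjustment is
    Benjamini-Hochberg over all genes.

    ``shrinkage`` selects the variance treatment: ``"moderated"`` (default)
    squeezes per-gene pooled variances toward a common prior by empirical
    Bayes, which restores power at tiny group sizes; ``"floor"`` floors each
    pooled variance at the 5th percentile of all pooled variances; ``None``
    is the ordinary pooled-variance t. In every mode a residual zero-variance
    gene gets p = 1 when its fold change is 0 and p = 0 otherwise.
    """
    if shrinkage not in ("moderated", "floor", None):
        raise ValueError("shrinkage must be 'moderated', 'floor' or None")
    cases = ds.samples_in(CASE)
    controls = ds.samples_in(CONTROL)
    for label, samples in ((CASE, cases), (CONTROL, controls)):
        if len(samples) < 2:
            raise ValueError(
                f"group '{label}' has {len(samples)} sample(s); need at least 2"
            )
    x = ds.values[cases].to_numpy(dtype=float)
    y = ds.values[controls].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    lfc = x.mean(axis=1) - y.mean(axis=1)
    s2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    df = float(n1 + n2 - 2)
    if shrinkage == "moderated":
        s2, df = _squeeze_variances(s2, df)
    elif shrinkage == "floor":
        s2 = np.maximum(s2, np.percentile(s2, 5))
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = se == 0
    if zero.any():
        t = np.where(zero, 0.0, t)
        p = np.where(zero, np.where(lfc == 0, 1.0, 0.0), p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": ds.gene_ids,
            "log2fc": lfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "regulation": np.where(lfc > 0, "Up", "Down"),
        }
    )
    return out.sort_values(["p_adj", "p", "gene"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass
class DEGFilter:
    """Fold-change and adjusted-p screen: |log2FC| > lfc_threshold (strict)
    and p_adj <= alpha (inclusive)."""

    lfc_threshold: float = 1.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class DEGSet:
    """Filtered DEG table plus the up/down gene partitions."""

    records: pd.DataFrame
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    @property
    def genes(self) -> set[str]:
        return self.up | self.down


def apply_deg_filter(records: pd.DataFrame, filt: DEGFilter | None = None) -> DEGSet:
    """Keep genes with |log2fc| > threshold (strict) and p_adj <= alpha."""
    if len(records) == 0:
        raise ValueError("no DEG records supplied")
    filt = filt or DEGFilter()
    keep = (
        (records["log2fc"].abs() > filt.lfc_threshold)
        & (records["p_adj"] <= filt.alpha)
    )
    kept = records[keep].reset_index(drop=True)
    return DEGSet(
        records=kept,
        up=set(kept.loc[kept["log2fc"] > 0, "gene"]),
        down=set(kept.loc[kept["log2fc"] <= 0, "gene"]),
    )


def intersect_and_merge(
    deg_sets: list[set[str] | DEGSet], datasets: list[ExpressionDataset]
) -> tuple[set[str], ExpressionDataset]:
    """Intersect DEG sets across datasets and merge the union into one matrix.

    The merged matrix covers the union of DEGs restricted to genes measured in
    every dataset; samples are concatenated with dataset provenance kept in
    the sample IDs (``<dataset>:<sample>``).
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least two DEG sets to intersect")
    sets = [s.genes if isinstance(s, DEGSet) else set(s) for s in deg_sets]
    union = set.union(*sets)
    if not union:
        raise ValueError("union of DEG sets is empty; nothing to merge")
    intersection = set.intersection(*sets)
    common = set.intersection(*(set(ds.gene_ids) for ds in datasets))
    genes = sorted(union & common)
    if not genes:
        raise ValueError("no merged DEG is measured in every dataset")
    blocks, groups = [], {}
    for ds in datasets:
        label = ds.name or f"ds{datasets.index(ds)}"
        block = ds.values.loc[genes].copy()
        block.columns = [f"{label}:{s}" for s in block.columns]
        blocks.append(block)
        for s in ds.sample_ids:
            groups[f"{label}:{s}"] = ds.groups[s]
    merged = ExpressionDataset(
        pd.concat(blocks, axis=1), pd.Series(groups), name="merged"
    )
    return intersection, merged
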