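"""Case-control SNP association from genotype counts.

Genotype tables (mm / Mm / MM per group, m = minor allele) yield 2x2 allele
tables, minor-allele frequency ratios with Katz log-scale confidence
intervals, Pearson chi-square allele tests, and dominant-model (carrier vs
non-carrier) exact tests. The frequency ratio is the headline statistic —
tables of this design are often printed with it labeled "OR" — and the
classical cross-product odds ratio with a Woolf CI is reported alongside,
clearly labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeTable",
    "AlleleTable",
    "AssociationResult",
    "allele_counts",
    "allele_ratio_ci",
    "odds_ratio_woolf",
    "allele_chi2",
    "dominant_test",
    "associate",
    "percent",
]

GENOTYPES = ("mm", "Mm", "MM")


def percent(count: int, total: int) -> str:
    """Percentage to 1 decimal place, round-half-up (e.g. 5/60 -> '8.3')."""
    frac = Decimal(count) * 100 / Decimal(total)
    return str(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class GenotypeTable:
    """Per-group genotype counts for one SNP (m = minor allele)."""

    snp: str
    minor: str
    major: str
    counts: dict[str, tuple[int, int, int]]  # group -> (mm, Mm, MM)

    def __post_init__(self) -> None:
        for group in ("case", "control"):
            if group not in self.counts:
                raise ValueError(f"counts missing group {group!r}")
            if any(c < 0 for c in self.counts[group]):
                raise ValueError("genotype counts must be >= 0")

    def group_n(self, group: str) -> int:
        return sum(self.counts[group])

    @classmethod
    def from_subjects(
        cls, calls: pd.DataFrame, snp: str, minor: str | None = None
    ) -> "GenotypeTable":
        """Aggregate per-subject genotype strings (e.g. "CG") for one SNP.

        Needs columns ``group`` (case/control) and ``genotype``; optionally a
        ``snp`` column to subset. The minor allele defaults to the rarer
        allele in the pooled sample, overridable via ``minor``.
        """
        df = calls[calls["snp"] == snp] if "snp" in calls.columns else calls
        if len(df) == 0:
            raise ValueError(f"no genotype calls for SNP {snp!r}")
        alleles: dict[str, int] = {}
        for gt in df["genotype"]:
            if len(gt) != 2:
                raise ValueError(f"malformed genotype {gt!r}; expect two alleles")
            for a in gt:
                alleles[a] = alleles.get(a, 0) + 1
        if len(alleles) > 2:
            raise ValueError(f"more than two alleles observed: {sorted(alleles)}")
        symbols = sorted(alleles, key=lambda a: (alleles[a], a))
        if minor is None:
            minor = symbols[0]
        if minor not in alleles:
            raise ValueError(f"declared minor allele {minor!r} never observed")
        major = next((a for a in symbols if a != minor), minor)
        counts = {}
        for group in ("case", "control"):
            sub = df[df["group"] == group]
            mm = int((sub["genotype"].apply(lambda g: g.count(minor)) == 2).sum())
            het = int((sub["genotype"].apply(lambda g: g.count(minor)) == 1).sum())
            hom = int((sub["genotype"].apply(lambda g: g.count(minor)) == 0).sum())
            counts[group] = (mm, het, hom)
        return cls(snp=snp, minor=minor, major=major, counts=counts)


@dataclass
class AlleleTable:
    """2x2 allele counts derived from genotypes: minor = 2*mm + Mm."""

    snp: str
    minor: str
    major: str
    case_minor: int
    case_major: int
    control_minor: int
    control_major: int

    @property
    def frequencies(self) -> dict[str, dict[str, float]]:
        out = {}
        for group, mn, mj in (
            ("case", self.case_minor, self.case_major),
            ("control", self.control_minor, self.control_major),
        ):
            total = mn + mj
            out[group] = {"minor": mn / total, "major": mj / total}
        return out

    @property
    def percent_strings(self) -> dict[str, dict[str, str]]:
        out = {}
        for group, mn, mj in (
            ("case", self.case_minor, self.case_major),
            ("control", self.control_minor, self.control_major),
        ):
            total = mn + mj
            out[group] = {"minor": percent(mn, total), "major": percent(mj, total)}
        return out


def allele_counts(table: GenotypeTable) -> AlleleTable:
    """Derive the 2x2 allele table and per-group allele frequencies."""
    mm_ca, het_ca, hom_ca = table.counts["case"]
    mm_co, het_co, hom_co = table.counts["control"]
    return AlleleTable(
        snp=table.snp,
        minor=table.minor,
        major=table.major,
        case_minor=2 * mm_ca + het_ca,
        case_major=2 * hom_ca + het_ca,
        control_minor=2 * mm_co + het_co,
        control_major=2 * hom_co + het_co,
    )


def allele_ratio_ci(
    at: AlleleTable, level: float = 0.95, allele: str = "minor"
) -> tuple[float, tuple[float, float] | None, bool]:
    """Allele-frequency ratio cases/controls with a Katz log-scale CI.

    ratio = (a/n1)/(c/n2) over allele totals; CI = exp(ln ratio ±
    z * sqrt(1/a - 1/n1 + 1/c - 1/n2)). Returns (ratio, (low, high),
    degenerate): a zero count in either group flags the result degenerate
    (ratio inf or 0, CI None) — no continuity correction is applied silently.
    """
    if allele == "minor":
        a, c = at.case_minor, at.control_minor
    elif allele == "major":
        a, c = at.case_major, at.control_major
    else:
        raise ValueError("allele must be 'minor' or 'major'")
    n1 = at.case_minor + at.case_major
    n2 = at.control_minor + at.control_major
    if c == 0:
        return float("inf"), None, True
    if a == 0:
        return 0.0, None, True
    ratio = (a / n1) / (c / n2)
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
    lo = float(np.exp(np.log(ratio) - z * se))
    hi = float(np.exp(np.log(ratio) + z * se))
    return float(ratio), (lo, hi), False


def odds_ratio_woolf(
    at: AlleleTable, level: float = 0.95
) -> tuple[float, tuple[float, float] | None, bool]:
    """Classical cross-product odds ratio with a Woolf log-scale CI."""
    a, b = at.case_minor, at.case_major
    c, d = at.control_minor, at.control_major
    if 0 in (a, b, c, d):
        if c == 0 or b == 0:
            return float("inf"), None, True
        return 0.0, None, True
    orr = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(orr),
        (float(np.exp(np.log(orr) - z * se)), float(np.exp(np.log(orr) + z * se))),
        False,
    )


def allele_chi2(at: AlleleTable) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) on the 2x2
    allele table."""
    obs = np.array(
        [[at.case_minor, at.case_major], [at.control_minor, at.control_major]]
    )
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin in allele table")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def dominant_test(table: GenotypeTable) -> dict:
    """Dominant-model (carrier mm+Mm vs non-carrier MM) association tests.

    Headline p is the two-sided Fisher exact test (sum of hypergeometric
    masses <= the observed mass); Pearson chi-square with and without Yates
    continuity correction and the 2x3 genotype chi-square are reported
    alongside for transparency.
    """
    mm_ca, het_ca, hom_ca = table.counts["case"]
    mm_co, het_co, hom_co = table.counts["control"]
    carriers = np.array(
        [[mm_ca + het_ca, hom_ca], [mm_co + het_co, hom_co]]
    )
    _, fisher_p = stats.fisher_exact(carriers, alternative="two-sided")
    out = {
        "model": "dominant (carrier mm+Mm vs MM)",
        "table": carriers,
        "fisher_p": float(fisher_p),
    }
    try:
        out["pearson_p"] = float(
            stats.chi2_contingency(carriers, correction=False)[1]
        )
        out["yates_p"] = float(stats.chi2_contingency(carriers, correction=True)[1])
    except ValueError:
        out["pearson_p"] = out["yates_p"] = float("nan")
    geno = np.array([[mm_ca, het_ca, hom_ca], [mm_co, het_co, hom_co]])
    cols = geno.sum(axis=0) > 0
    try:
        out["genotype_2x3_p"] = float(
            stats.chi2_contingency(geno[:, cols], correction=False)[1]
        )
    except ValueError:
        out["genotype_2x3_p"] = float("nan")
    return out


@dataclass
class AssociationResult:
    snp: str
    allele_ratio: float
    ci95: tuple[float, float] | None
    allele_p: float
    allele_chi2: float
    major_ratio: float
    major_ci95: tuple[float, float] | None
    odds_ratio: float
    odds_ci95: tuple[float, float] | None
    dominant_p: float
    dominant_tests: dict = field(default_factory=dict)
    frequencies: dict = field(default_factory=dict)
    percent_strings: dict = field(default_factory=dict)
    degenerate: bool = False


def associate(table: GenotypeTable, level: float = 0.95) -> AssociationResult:
    """Full association summary for one SNP from genotype counts."""
    at = allele_counts(table)
    ratio, ci, degen_minor = allele_ratio_ci(at, level, "minor")
    major, major_ci, degen_major = allele_ratio_ci(at, level, "major")
    orr, or_ci, _ = odds_ratio_woolf(at, level)
    try:
        chi2, p = allele_chi2(at)
    except ValueError:  # fully degenerate table (zero margin)
        chi2, p = float("nan"), float("nan")
    dom = dominant_test(table)
    return AssociationResult(
        snp=table.snp,
        allele_ratio=ratio,
        ci95=ci,
        allele_p=p,
        allele_chi2=chi2,
        major_ratio=major,
        major_ci95=major_ci,
        odds_ratio=orr,
        odds_ci95=or_ci,
        dominant_p=dom["fisher_p"],
        dominant_tests=dom,
        frequencies=at.frequencies,
        percent_strings=at.percent_strings,
        degenerate=degen_minor or degen_major,
    )
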