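"""Diagnostic and prognostic biomarker evaluation.

ROC/AUC measures how well a gene's expression separates cases from controls
(AUC = probability a random case outscores a random control, ties
half-credited). Prognosis is assessed by a median split of expression into
high/low groups, Kaplan-Meier curves per group, and the two-sample log-rank
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["RocResult", "KMResult", "roc_auc", "km_logrank"]


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray = field(default=None, repr=False)

    @property
    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(
    scores, labels, case_label="case", higher_is_case: bool = True
) -> RocResult:
    """Empirical ROC curve and AUC for one score vector.

    ``labels`` may be booleans or group labels equal to ``case_label`` for
    cases. ``higher_is_case=False`` inverts the score direction for genes
    where low expression marks disease.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels if labels.dtype == bool else labels == case_label
    if y.all() or not y.any():
        raise ValueError("need both cases and controls to build a ROC curve")
    s = scores if higher_is_case else -scores
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return RocResult(auc=float(roc_auc_score(y, s)), fpr=fpr, tpr=tpr,
                     thresholds=thr)


@dataclass
class KMResult:
    chi2: float
    p: float
    groups: pd.Series  # sample -> "high" | "low"
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    median_split_value: float = float("nan")


def km_logrank(
    expression: pd.Series, survival: pd.DataFrame, split: str = "median"
) -> KMResult:
    """Median-split Kaplan-Meier comparison of survival by expression level.

    ``survival`` needs columns ``time`` (positive, e.g. months) and ``event``
    (1 = death, 0 = censored), indexed by (or carrying a ``sample`` column
    matching) the samples of ``expression``. Samples exactly at the median go
    to the low group, making the split deterministic. Returns per-group
    product-limit curves plus the log-rank chi-square (df = 1) and p-value.
    """
    if split != "median":
        raise ValueError("only the median split rule is supported")
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    common = [s for s in expression.index if s in surv.index]
    if not common:
        raise ValueError("no shared samples between expression and survival")
    expr = expression.loc[common].astype(float)
    surv = surv.loc[common]
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    cut = float(np.median(expr))
    groups = pd.Series(
        np.where(expr > cut, "high", "low"), index=expr.index, name="group"
    )
    n_high, n_low = int((groups == "high").sum()), int((groups == "low").sum())
    if n_high < 2 or n_low < 2:
        raise ValueError(
            f"degenerate median split: {n_high} high / {n_low} low samples"
        )
    curves = {}
    for label in ("high", "low"):
        mask = groups == label
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask, "time"], surv.loc[mask, "event"], label=label)
        curves[label] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", label: "survival"}
        )
    res = logrank_test(
        surv.loc[groups == "high", "time"],
        surv.loc[groups == "low", "time"],
        event_observed_A=surv.loc[groups == "high", "event"],
        event_observed_B=surv.loc[groups == "low", "event"],
    )
    return KMResult(
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        groups=groups,
        curves=curves,
        median_split_value=cut,
    )
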