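"""Radiological-pathological concordance and cohort statistics.

The positive class throughout is remyelination: MRI-predicted versus
histologically confirmed remyelination is cross-tabulated into a 2x2
confusion matrix (early-active and chronic lesions collapse to
"demyelinated"), from which sensitivity and specificity follow. Interrater
agreement uses Cohen's kappa; the corticosteroid effect uses the
point-biserial correlation (with an exact permutation p for binary
outcomes); lesion-age/OPC association uses Pearson correlation; group
comparisons use Welch's t-test or one-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DEMYELINATED_CLASSES, LesionClass, as_lesion_class

logger = logging.getLogger(__name__)

#: Required columns of a lesion label table.
LABEL_TABLE_COLUMNS = (
    "subject", "lesion_id", "mri_category", "histo_category",
    "steroid_treated", "lesion_age_weeks", "opc_count",
)


@dataclass
class ConfusionMatrix2x2:
    """Demyelinated-vs-remyelinated concordance counts.

    Positive class is remyelination: ``tp`` = remyelinated on both MRI and
    histology, ``fp`` = MRI remyelinated / histology demyelinated, ``fn`` =
    MRI demyelinated / histology remyelinated, ``tn`` = demyelinated on
    both.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def binarize_and_tabulate(table: pd.DataFrame) -> ConfusionMatrix2x2:
    """Cross-tabulate MRI vs histology remyelination calls.

    Rows lacking a histology category (NaN/None) are excluded; the excluded
    count is logged. Three-level categories collapse to remyelinated vs
    demyelinated.
    """
    if "mri_category" not in table or "histo_category" not in table:
        raise ValueError("table must have mri_category and histo_category columns")
    usable = table.dropna(subset=["histo_category"])
    n_excluded = len(table) - len(usable)
    if n_excluded:
        logger.info("binarize_and_tabulate: excluded %d rows without histology",
                    n_excluded)
    tp = fn = fp = tn = 0
    for _, row in usable.iterrows():
        mri_remyel = as_lesion_class(row["mri_category"]) is LesionClass.REMYELINATED
        histo_remyel = as_lesion_class(row["histo_category"]) is LesionClass.REMYELINATED
        if mri_remyel and histo_remyel:
            tp += 1
        elif mri_remyel and not histo_remyel:
            fp += 1
        elif not mri_remyel and histo_remyel:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix2x2(tp=tp, fn=fn, fp=fp, tn=tn)


def sensitivity_specificity(cm: ConfusionMatrix2x2) -> Tuple[float, float]:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) for remyelination."""
    if cm.tp + cm.fn == 0:
        raise ValueError("sensitivity undefined: no histologically remyelinated lesions")
    if cm.tn + cm.fp == 0:
        raise ValueError("specificity undefined: no histologically demyelinated lesions")
    return cm.tp / (cm.tp + cm.fn), cm.tn / (cm.tn + cm.fp)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two raters' categorical labels.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and p_e
    the chance agreement from the product of marginal label frequencies.
    Returns 1.0 in the degenerate perfect-agreement case p_e = p_o = 1.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least 2 items")
    n = len(a)
    cats = sorted(set(a) | set(b), key=str)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def point_biserial(binary: Sequence, values: Sequence[float]) -> Tuple[float, float]:
    """Point-biserial correlation between a binary variable and an outcome.

    The binary variable is coded 0/1; r is the Pearson correlation and the
    two-sided p-value comes from the t transform with n-2 degrees of
    freedom. Raises for zero-variance inputs.
    """
    x = np.asarray(binary, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("point-biserial correlation undefined for constant input")
    res = sps.pointbiserialr(x, y)
    return float(res.statistic), float(res.pvalue)


def point_biserial_permutation_p(
    binary: Sequence, values: Sequence[float],
    n_resamples: int = 10000, seed: int = 0,
) -> float:
    """Permutation p-value for the point-biserial correlation.

    For a binary outcome the null distribution of r given the margins is a
    function of the hypergeometric count of positive outcomes in group 1,
    so the two-sided p is computed exactly by enumeration. Otherwise a
    Monte-Carlo permutation test with ``n_resamples`` shuffles is used.
    """
    x = np.asarray(binary, dtype=float)
    y = np.asarray(values, dtype=float)
    r_obs, _ = point_biserial(x, y)
    uniq = np.unique(y)
    if len(uniq) == 2:
        y01 = (y == uniq[1]).astype(int)
        n = len(y01)
        n1 = int(np.sum(x == np.max(x)))  # group-1 size
        total_pos = int(y01.sum())
        p = 0.0
        lo = max(0, total_pos - (n - n1))
        hi = min(n1, total_pos)
        for k in range(lo, hi + 1):
            yk = np.concatenate([
                np.ones(k), np.zeros(n1 - k),
                np.ones(total_pos - k), np.zeros(n - n1 - (total_pos - k)),
            ])
            xk = np.concatenate([np.ones(n1), np.zeros(n - n1)])
            r_k = np.corrcoef(xk, yk)[0, 1]
            if abs(r_k) >= abs(r_obs) - 1e-12:
                p += sps.hypergeom.pmf(k, n, total_pos, n1)
        return float(min(1.0, p))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        r_p = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(r_p) >= abs(r_obs) - 1e-12:
            count += 1
    return (count + 1) / (n_resamples + 1)


def correlate_age_opc(table: pd.DataFrame) -> Tuple[float, float]:
    """Pearson correlation between lesion age (weeks) and OPC count.

    Young, early-active lesions mount a proliferative OPC response, so the
    expected association is negative.
    """
    usable = table.dropna(subset=["lesion_age_weeks", "opc_count"])
    if len(usable) < 3:
        raise ValueError(f"need >= 3 lesions with age and OPC count, got {len(usable)}")
    res = sps.pearsonr(usable["lesion_age_weeks"].astype(float),
                       usable["opc_count"].astype(float))
    return float(res.statistic), float(res.pvalue)


def group_compare(
    values_by_group: Dict[str, Sequence[float]],
    test: str = "t_test",
    equal_var: bool = False,
) -> Tuple[float, float]:
    """Two-sample t-test (Welch by default) or one-way ANOVA across groups.

    Returns (statistic, p). ``t_test`` requires exactly two groups; every
    group needs at least 2 values.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if test == "t_test":
        if len(groups) != 2:
            raise ValueError(f"t_test requires exactly 2 groups, got {len(groups)}")
        res = sps.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        return float(res.statistic), float(res.pvalue)
    if test == "anova":
        res = sps.f_oneway(*groups)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}; expected 't_test' or 'anova'")


def validate_label_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a lesion label table; returns the validated frame."""
    missing = [c for c in LABEL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"label table missing required columns: {missing}")
    return table


def concordance_report(
    table: pd.DataFrame,
    stated_specificity_pct: Optional[float] = None,
) -> dict:
    """Evaluation report: confusion matrix, sensitivity/specificity, subgroup rates.

    If ``stated_specificity_pct`` is given (an externally reported value),
    the report compares it with the table-derived specificity and sets
    ``specificity_discrepancy`` when they differ by more than 1 percentage
    point — the table cells are authoritative.
    """
    cm = binarize_and_tabulate(table)
    try:
        sens, spec = sensitivity_specificity(cm)
    except ValueError:  # a class absent from the histology labels
        sens = spec = float("nan")
    report = {
        "n_lesions": cm.total,
        "confusion_matrix": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "sensitivity_pct": 100.0 * sens,
        "specificity_pct": 100.0 * spec,
        "accuracy_pct": 100.0 * cm.accuracy,
    }
    if stated_specificity_pct is not None:
        report["stated_specificity_pct"] = float(stated_specificity_pct)
        report["specificity_discrepancy"] = (
            abs(report["specificity_pct"] - stated_specificity_pct) > 1.0
        )
    if "mri_category" in table:
        mri_remyel = table["mri_category"].map(
            lambda v: as_lesion_class(v) is LesionClass.REMYELINATED
        )
        report["mri_remyelinated_pct"] = 100.0 * float(mri_remyel.mean())
        if "steroid_treated" in table and table["steroid_treated"].notna().all():
            treated = table["steroid_treated"].astype(bool)
            for flag, name in ((True, "treated"), (False, "untreated")):
                sub = mri_remyel[treated == flag]
                if len(sub):
                    report[f"{name}_remyelinated_pct"] = 100.0 * float(sub.mean())
    return report
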