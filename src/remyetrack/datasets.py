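"""Reference cohort tables from a six-marmoset EAE serial-MRI study.

These are the published per-animal lesion classification counts, the
lesion-level radiological-pathological confusion matrix, and the
corticosteroid subgroup counts of the reference cohort: six marmosets with
experimental autoimmune encephalomyelitis followed with weekly 7T MRI
until sacrifice, 40 focal white-matter lesions classified on PDw MRI and
31 on histology (one animal's tissue could not be processed). They serve
as worked-example inputs for the concordance statistics.
"""

from __future__ import annotations

import pandas as pd

from .stats import ConfusionMatrix2x2

#: Per-animal lesion counts classified on serial PDw MRI.
MRI_CLASSIFICATION_COUNTS = pd.DataFrame(
    {
        "animal": ["M1", "M2", "M3", "M4", "M5", "M6"],
        "early_active": [1, 1, 1, 0, 3, 6],
        "chronic_demyelinated": [2, 1, 1, 1, 3, 2],
        "remyelinated": [6, 6, 4, 2, 0, 0],
    }
)

#: Per-animal lesion counts classified on histopathology (no tissue for M1).
HISTO_CLASSIFICATION_COUNTS = pd.DataFrame(
    {
        "animal": ["M2", "M3", "M4", "M5", "M6"],
        "early_active": [1, 1, 0, 3, 7],
        "chronic_demyelinated": [3, 1, 2, 3, 1],
        "remyelinated": [4, 4, 1, 0, 0],
    }
)

#: Lesion-level demyelinated-vs-remyelinated concordance (positive class =
#: remyelination): 9 concordant remyelinated, 19 concordant demyelinated,
#: 3 MRI-remyelinated/histology-demyelinated, none the other way.
CONFUSION_DEMYEL_VS_REMYEL = ConfusionMatrix2x2(tp=9, fn=0, fp=3, tn=19)

#: MRI-predicted remyelination by corticosteroid treatment status:
#: (remyelinated lesions, total lesions) per subgroup.
STEROID_SUBGROUPS = {
    "treated": (10, 21),
    "untreated": (8, 19),
}

#: Summary values stated for the reference cohort (for cross-checking
#: against the table-derived quantities; the table cells are authoritative).
STATED_SUMMARY = {
    "sensitivity_pct": 100.0,
    "specificity_pct": 90.0,
    "interrater_agreement_pct": 94.0,
    "interrater_kappa": 0.89,
    "steroid_point_biserial_p": 0.8,
    "age_opc_pearson_r": -0.46,
    "age_opc_pearson_p": 0.009,
}


def mri_class_proportions() -> pd.Series:
    """Cohort-level MRI class proportions (sum to 1 over the three classes)."""
    counts = MRI_CLASSIFICATION_COUNTS[
        ["early_active", "chronic_demyelinated", "remyelinated"]
    ].sum()
    return counts / counts.sum()


def steroid_binary_vectors() -> tuple:
    """Per-lesion (treated, remyelinated) 0/1 vectors for the steroid analysis."""
    treated, remyel = [], []
    for name, (k, n) in STEROID_SUBGROUPS.items():
        flag = 1 if name == "treated" else 0
        treated.extend([flag] * n)
        remyel.extend([1] * k + [0] * (n - k))
    return treated, remyel
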