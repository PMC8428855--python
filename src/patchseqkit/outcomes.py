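"""ROC/AUC analysis of experiment covariates against binary outcomes.

Links acquisition covariates — end-pipette resistance (endR), cDNA
quantity and quality, NMS — to binary outcomes such as nucleus
retrieval, morphology success, or mapping consistency.  The score
direction is always explicit (endR: higher predicts a good morphology
outcome; NMS: higher predicts pass), never inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

__all__ = ["ROCResult", "roc_auc", "operating_point", "group_ttest"]

GOOD_MORPHOLOGY = ("high", "medium")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels, direction: str = "greater") -> ROCResult:
    """Empirical ROC over all thresholds, AUC by the trapezoid rule.

    ``direction="greater"`` means higher scores indicate the positive
    label; ``"less"`` flips the orientation.  Equal scores are grouped
    into a single step.  Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    s = scores if direction == "greater" else -scores
    fpr, tpr, thr = roc_curve(labels, s)
    if direction == "less":
        thr = -thr
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


def operating_point(
    scores, labels, cutoff: float, direction: str = "greater"
) -> tuple[float, float]:
    """(fraction of negative-outcome cells excluded, fraction of positive lost).

    With ``direction="greater"`` a cell is excluded when its score falls
    below the cutoff; the first fraction is the benefit (bad outcomes
    screened out), the second the cost (good outcomes lost).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    excluded = scores < cutoff if direction == "greater" else scores > cutoff
    neg, pos = ~labels, labels
    frac_bad = float(excluded[neg].mean()) if neg.any() else 0.0
    frac_good = float(excluded[pos].mean()) if pos.any() else 0.0
    return frac_bad, frac_good


def group_ttest(values, groups) -> tuple[float, float]:
    """Convenience Welch t-test between two groups; (statistic, p-value)."""
    from scipy.stats import ttest_ind

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(bool)
    res = ttest_ind(values[groups], values[~groups], equal_var=False)
    return float(res.statistic), float(res.pvalue)


def morphology_labels(meta: pd.DataFrame) -> pd.Series:
    """Binary good-morphology label (high/medium vs failed); others dropped."""
    keep = meta["morphology_outcome"].isin(GOOD_MORPHOLOGY + ("failed",))
    sub = meta.loc[keep]
    return sub["morphology_outcome"].isin(GOOD_MORPHOLOGY)
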