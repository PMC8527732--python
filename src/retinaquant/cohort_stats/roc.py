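"""Empirical ROC analysis with a Youden-index cutoff."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RocResult:
    parameter: str
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    criterion: str = "youden"
    #: True when low parameter values indicate the positive outcome.
    lower_is_abnormal: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise ValueError("sensitivity/specificity must lie in [0, 1]")


def _empirical_roc(
    scores: np.ndarray, positive: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """TPR/FPR at every observed threshold (score >= t is called positive)."""
    thresholds = np.unique(scores)[::-1]
    n_pos = positive.sum()
    n_neg = (~positive).sum()
    tpr = np.array([(scores[positive] >= t).sum() / n_pos for t in thresholds])
    fpr = np.array([(scores[~positive] >= t).sum() / n_neg for t in thresholds])
    return thresholds, tpr, fpr


def _trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    fpr = np.concatenate(([0.0], fpr, [1.0]))
    tpr = np.concatenate(([0.0], tpr, [1.0]))
    return float(np.trapezoid(tpr, fpr))


def roc_cutoff(
    records: pd.DataFrame,
    parameter: str,
    outcome: str = "bcva_decreased",
) -> RocResult:
    """Empirical ROC of one parameter against a binary outcome.

    The abnormal direction is auto-detected: if calling high values
    positive yields AUC < 0.5, the scale is flipped (low-is-abnormal).
    The reported cutoff maximises Youden's J = sensitivity + specificity
    - 1; with the flipped scale the rule is ``value <= cutoff``.
    """
    scores = np.asarray(records[parameter], dtype=float)
    positive = np.asarray(records[outcome]).astype(bool)
    if positive.all() or not positive.any():
        raise ValueError("outcome must contain both classes")
    lower_is_abnormal = False
    _, tpr, fpr = _empirical_roc(scores, positive)
    auc = _trapezoid_auc(fpr, tpr)
    if auc < 0.5:
        lower_is_abnormal = True
        scores = -scores
        _, tpr, fpr = _empirical_roc(scores, positive)
        auc = _trapezoid_auc(fpr, tpr)
    thresholds, tpr, fpr = _empirical_roc(scores, positive)
    j = tpr - fpr
    k = int(np.argmax(j))
    cutoff = float(thresholds[k])
    if lower_is_abnormal:
        cutoff = -cutoff
    return RocResult(
        parameter=parameter,
        auc=auc,
        cutoff=cutoff,
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
        lower_is_abnormal=lower_is_abnormal,
    )
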