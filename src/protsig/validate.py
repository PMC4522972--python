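"""Validate a signature score against proteomic truth: correlation and ROC.

The headline questions are (i) does the score track the continuous protein
value (Pearson correlation) and (ii) can it classify protein-positive vs
protein-negative samples (ROC/AUC)?  The AUC is computed as the two-sample
Mann-Whitney U statistic divided by n_pos*n_neg (ties counted 1/2), with a
two-sided normal-approximation Mann-Whitney p-value against AUC = 0.5; the
ROC curve itself comes from a threshold sweep over the observed scores, and
its trapezoidal area equals the U-based AUC identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .datatypes import HIGH, LOW, GroupLabels, SignatureScoreVector
from .exceptions import DegenerateDataError, ValidationError


def pearson_correlation(x, y) -> Tuple[float, float]:
    """Pearson r and its two-sided p-value from the t-transform.

    Pairs with a missing value in either vector are dropped.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValidationError("pearson_correlation needs >=3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ROCResult:
    """AUC with Mann-Whitney significance and the swept ROC curve."""

    auc: float
    p_value: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def curve(self) -> list:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "p_value": self.p_value,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "curve": self.curve,
        }


def roc_auc(scores, truth: GroupLabels) -> ROCResult:
    """ROC of a score against binary protein truth labels.

    ``truth`` samples labeled ``excluded`` are dropped.  AUC = U/(n_pos *
    n_neg) with ties counted 1/2; p-value from the two-sided
    normal-approximation Mann-Whitney test of AUC = 0.5 (1.0 when all
    scores are tied and the test is degenerate).
    """
    series = scores.scores if isinstance(scores, SignatureScoreVector) else pd.Series(scores)
    labels = truth.labels if isinstance(truth, GroupLabels) else pd.Series(truth)
    common = series.index.intersection(labels.index)
    series = series.loc[common]
    labels = labels.loc[common]
    pos = series[labels == HIGH].to_numpy(dtype=float)
    neg = series[labels == LOW].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("roc_auc needs at least one high and one low truth label")
    if len(np.unique(np.concatenate([pos, neg]))) == 1:
        auc, p = 0.5, 1.0
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        return ROCResult(auc, p, len(pos), len(neg), fpr, tpr)
    mwu = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = float(mwu.statistic) / (len(pos) * len(neg))
    y_true = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    y_score = np.concatenate([pos, neg])
    fpr, tpr, _ = roc_curve(y_true, y_score, drop_intermediate=False)
    return ROCResult(auc, float(mwu.pvalue), len(pos), len(neg), fpr, tpr)
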