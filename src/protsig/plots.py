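"""Basic Kaplan-Meier and ROC figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .survival import KMCurve
from .validate import ROCResult


def plot_km(curves: dict, ax=None, title: str = "Kaplan-Meier"):
    """Step plot of one or more KM curves (dict label -> KMCurve)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        if not isinstance(curve, KMCurve):
            raise TypeError("plot_km expects KMCurve values")
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=str(label))
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend()
    return ax


def plot_roc(roc: ROCResult, ax=None, title: str = "ROC"):
    """ROC curve with the chance diagonal and the AUC in the legend."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.3f} (p = {roc.p_value:.3g})")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    return ax
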