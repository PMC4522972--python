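"""Association screens: correlation tables and the stromal-group rank test.

``correlation_screen`` correlates a target variable (signature score or a
protein) against each feature of a panel with pairwise-complete missing
handling and joint BH-FDR across features.  ``mann_whitney_one_tailed``
compares scores between two pathologist-defined groups (e.g. low vs
moderate/high stromal reactivation) with an exact one-tailed p-value for
small tie-free samples and a tie/continuity-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .derive import benjamini_hochberg
from .exceptions import ValidationError
from .validate import pearson_correlation

logger = logging.getLogger(__name__)

#: exact Mann-Whitney enumeration is used up to this n_A * n_B (tie-free)
EXACT_LIMIT = 400


def correlation_screen(target: pd.Series, features: pd.DataFrame) -> pd.DataFrame:
    """Pearson r, p and BH-FDR of a target against each feature column.

    Features with fewer than 3 complete pairs against the target, or with
    zero variance on the complete pairs, are excluded (with a logged
    reason), not errors: RPPA panels routinely have per-antibody dropouts.
    """
    if not isinstance(target, pd.Series):
        target = pd.Series(target)
    features = features.reindex(target.index)
    rows = {}
    skipped = []
    for name, col in features.items():
        pair = pd.concat([target, col], axis=1).dropna()
        if len(pair) < 3:
            skipped.append((name, "fewer than 3 complete pairs"))
            continue
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            skipped.append((name, "zero variance"))
            continue
        r, p = pearson_correlation(x, y)
        rows[name] = {"r": r, "p": p, "n": len(pair)}
    for name, reason in skipped:
        logger.info("correlation_screen: skipped feature %s (%s)", name, reason)
    if not rows:
        raise ValidationError("no feature had >=3 complete, non-constant pairs")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "feature"
    table["fdr"] = benjamini_hochberg(table["p"].to_numpy())
    return table.sort_values("p")


def correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Symmetric pairwise-complete Pearson correlation matrix (diagonal 1)."""
    return features.corr(method="pearson", min_periods=3)


def mann_whitney_one_tailed(
    scores_a, scores_b, alternative: str = "B_greater"
) -> Tuple[float, float]:
    """One-tailed Mann-Whitney U test between two score groups.

    Parameters
    ----------
    scores_a, scores_b : array-like
        The two groups (e.g. low vs pooled moderate/high stromal
        reactivation).
    alternative : {"B_greater", "A_greater"}
        Direction of the one-sided alternative.

    Returns
    -------
    (U, p_value)
        U is the statistic of group A (number of (a, b) pairs with a > b,
        ties counting 1/2).  The p-value is exact (full enumeration) when
        n_A * n_B <= 400 and there are no ties, otherwise a normal
        approximation with tie and continuity corrections.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("mann_whitney_one_tailed needs non-empty groups")
    if alternative == "B_greater":
        scipy_alt = "less"  # A stochastically smaller than B
    elif alternative == "A_greater":
        scipy_alt = "greater"
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=scipy_alt, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)
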