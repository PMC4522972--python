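"""Dichotomize samples on a per-sample protein value (RPPA readout).

Three rules are supported, matching the three ways phosphoprotein status is
turned into discrete groups in this kind of analysis:

* :func:`quartile_groups` — upper vs lower quartile, middle half excluded;
  used when deriving a signature from samples with clear up/down protein
  expression.
* :func:`zscore_groups` — z > +t vs z < -t (default t = 0.2); the grouping
  used for level-3 consortium RPPA data.
* :func:`sd_groups` — above mean + k*SD vs below mean - k*SD (default
  k = 1); the truth labels for ROC validation.

All three return a :class:`~protsig.datatypes.GroupLabels` partition of the
input samples into high / low / excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import EXCLUDED, HIGH, LOW, GroupLabels
from .exceptions import DegenerateDataError, ValidationError


def _clean(protein: pd.Series) -> pd.Series:
    if not isinstance(protein, pd.Series):
        protein = pd.Series(protein)
    return protein.dropna().astype(float)


def quartile_groups(protein: pd.Series) -> GroupLabels:
    """Label samples at or above Q3 high, at or below Q1 low, rest excluded.

    Quartiles use linear-interpolation quantiles (the p-quantile of sorted
    x1..xn interpolates at index (n-1)p).  Values exactly on a cutoff join
    the extreme group, so each group has at least n/4 members.
    """
    values = _clean(protein)
    if len(values) < 8:
        raise ValidationError(
            f"quartile grouping needs >=8 non-missing values, got {len(values)}"
        )
    q1, q3 = np.quantile(values.to_numpy(), [0.25, 0.75], method="linear")
    if q1 == q3:
        raise DegenerateDataError("no separation: Q1 equals Q3")
    labels = pd.Series(EXCLUDED, index=values.index, dtype=object)
    labels[values >= q3] = HIGH
    labels[values <= q1] = LOW
    return GroupLabels(labels)


def zscore_groups(protein: pd.Series, threshold: float = 0.2) -> GroupLabels:
    """Label samples by z-score: z > threshold high, z < -threshold low.

    z uses the sample SD (n-1 denominator).  Samples with |z| <= threshold
    are excluded.
    """
    values = _clean(protein)
    if len(values) < 3:
        raise ValidationError("z-score grouping needs >=3 non-missing values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero standard deviation")
    z = (values - values.mean()) / sd
    labels = pd.Series(EXCLUDED, index=values.index, dtype=object)
    labels[z > threshold] = HIGH
    labels[z < -threshold] = LOW
    return GroupLabels(labels)


def sd_groups(protein: pd.Series, k: float = 1.0) -> GroupLabels:
    """Label samples above mean + k*SD high and below mean - k*SD low.

    The symmetric mean +/- k*SD cutoffs define protein-positive and
    protein-negative truth groups for ROC validation; the bulk in between
    is excluded.
    """
    values = _clean(protein)
    if len(values) < 3:
        raise ValidationError("SD grouping needs >=3 non-missing values")
    mean, sd = values.mean(), values.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero standard deviation")
    labels = pd.Series(EXCLUDED, index=values.index, dtype=object)
    labels[values > mean + k * sd] = HIGH
    labels[values < mean - k * sd] = LOW
    return GroupLabels(labels)


_METHODS = {
    "quartile": quartile_groups,
    "zscore": zscore_groups,
    "sd": sd_groups,
}


def group_samples(protein: pd.Series, method: str = "quartile", **kwargs) -> GroupLabels:
    """Dispatch to one of the grouping rules by name."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown grouping method {method!r}") from None
    return fn(protein, **kwargs)
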