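"""Signature scoring: the signed-sum score and its dichotomization.

The score of sample j for a signed signature S = {(gene_i, s_i)} is the
scalar product

    score_j = sum_i s_i * e_ij

with e_ij the (log-scale) expression of gene i in sample j.  By default the
raw formula is used; per-gene z-scoring (``standardize``) and division by the
number of matched genes (``scale_by_n``) are available for cross-platform
transfer, where absolute intensities are not comparable.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSignature, SignatureScoreVector
from .exceptions import DegenerateDataError, ValidationError


def score_samples(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    standardize: bool = False,
    scale_by_n: bool = False,
) -> SignatureScoreVector:
    """Compute the signed-sum signature score for every sample.

    Signature genes absent from the matrix are skipped and reported in
    ``missing_genes``.  Missing expression values are treated as 0
    contribution after standardization, or dropped from the raw sum.
    """
    if len(signature) == 0:
        raise ValidationError("cannot score with an empty signature")
    present = [g for g, _ in signature.entries if g in matrix.data.index]
    missing = [g for g, _ in signature.entries if g not in matrix.data.index]
    if not present:
        sample = list(matrix.data.index[:5])
        raise ValidationError(
            f"no signature gene found in the matrix; signature genes "
            f"{signature.genes[:5]}..., matrix symbols look like {sample}"
        )
    coefs = signature.coefficients.loc[present].to_numpy(dtype=float)
    values = matrix.data.loc[present].to_numpy(dtype=float)
    if standardize:
        mean = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        values = (values - mean) / sd
    contrib = coefs[:, None] * values
    scores = np.nansum(contrib, axis=0)
    if scale_by_n:
        scores = scores / len(present)
    return SignatureScoreVector(
        scores=pd.Series(scores, index=matrix.data.columns, name="score"),
        matched_genes=len(present),
        missing_genes=missing,
        standardized=standardize,
        signature_name=signature.name,
    )


def dichotomize_scores(
    scores: SignatureScoreVector,
    method: str = "median",
    stratify_by: Optional[pd.Series] = None,
) -> pd.Series:
    """Split scores into high/low at the median (ties go low).

    With ``stratify_by`` given (e.g. ER status), the median is computed
    within each stratum, so each stratum is split at its own midpoint.
    """
    if method != "median":
        raise ValueError(f"unknown dichotomization method {method!r}")
    series = scores.scores if isinstance(scores, SignatureScoreVector) else pd.Series(scores)
    if len(series) < 2:
        raise ValidationError("dichotomization needs >=2 samples")
    if series.nunique() == 1:
        raise DegenerateDataError("all scores identical; cannot dichotomize")

    def split(values: pd.Series) -> pd.Series:
        med = float(np.median(values.to_numpy(dtype=float)))
        return pd.Series(np.where(values > med, "high", "low"), index=values.index)

    if stratify_by is None:
        return split(series).rename("score_group")
    strata = stratify_by.reindex(series.index)
    parts = [split(series[strata == level]) for level in strata.dropna().unique()]
    out = pd.concat(parts) if parts else pd.Series(dtype=object)
    return out.reindex(series.index).rename("score_group")
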