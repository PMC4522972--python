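"""Core in-memory containers for the signature pipeline.

The pipeline moves four kinds of objects between stages: a gene-by-sample
expression matrix (log-scale intensities), a signed gene signature
(coefficients in {-1, +1}), per-sample group labels from protein
dichotomization, and a clinical table with right-censored survival
endpoints.  All containers are thin, validated wrappers over pandas
structures so any stage can also be driven directly from DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

HIGH = "high"
LOW = "low"
EXCLUDED = "excluded"

ER_LEVELS = ("pos", "neg", "unknown")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Missing measurements are stored as NaN, never imputed here; each
    downstream operation declares its own missing-value policy.
    """

    data: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size and np.isinf(values).any():
            raise ValidationError("expression values must be finite or NaN")

    @property
    def gene_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GeneSignature:
    """Ordered signed gene set: each gene carries a coefficient of -1 or +1.

    +1 marks up-regulation in the protein-high group, -1 down-regulation.
    An empty signature is representable (derivation on null data) but most
    consumers reject it.
    """

    entries: tuple  # tuple of (gene: str, coefficient: int)
    name: str = "signature"

    def __post_init__(self):
        entries = []
        seen = set()
        for gene, coef in self.entries:
            gene = str(gene).strip()
            if not gene:
                raise ValidationError("empty gene symbol in signature")
            if gene in seen:
                raise ValidationError(f"duplicate gene in signature: {gene}")
            seen.add(gene)
            if coef not in (-1, 1):
                raise ValidationError(
                    f"signature coefficient for {gene} must be -1 or +1, got {coef}"
                )
            entries.append((gene, int(coef)))
        self.entries = tuple(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneSignature)
            and self.entries == other.entries
            and self.name == other.name
        )

    @property
    def genes(self) -> list:
        return [g for g, _ in self.entries]

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(
            {g: c for g, c in self.entries}, dtype=int, name=self.name
        )


@dataclass
class GroupLabels:
    """Per-sample protein dichotomization labels: high / low / excluded."""

    labels: pd.Series  # index: sample ids, values in {high, low, excluded}

    def __post_init__(self):
        if not isinstance(self.labels, pd.Series):
            self.labels = pd.Series(self.labels)
        bad = set(self.labels.unique()) - {HIGH, LOW, EXCLUDED}
        if bad:
            raise ValidationError(f"invalid group labels: {sorted(bad)}")
        if self.labels.index.has_duplicates:
            raise ValidationError("duplicate sample ids in group labels")

    def samples(self, label: str) -> list:
        return self.labels.index[self.labels == label].tolist()

    @property
    def n_high(self) -> int:
        return int((self.labels == HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == LOW).sum())


#: Columns a clinical table is expected to provide (besides the sample index).
CLINICAL_COLUMNS = (
    "time",
    "event",
    "treatment",
    "er_status",
    "age",
    "tumor_size",
    "grade",
    "nodal_status",
)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and a right-censored survival endpoint.

    ``time`` is in months from randomization; ``event`` is 1 for an observed
    endpoint event and 0 for censoring; ``treatment`` is the randomized arm
    (1 = treated).  Rows with missing time or event are kept but flagged via
    :attr:`usable_for_survival`.
    """

    data: pd.DataFrame  # index: sample ids

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("clinical table must be a DataFrame")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValidationError(f"clinical table missing column '{col}'")
        time = self.data["time"]
        if (time.dropna() < 0).any():
            raise ValidationError("negative survival time")
        ev = self.data["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        if "er_status" in self.data.columns:
            er = self.data["er_status"].dropna()
            bad = set(er.unique()) - set(ER_LEVELS)
            if bad:
                raise ValidationError(f"invalid er_status values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def usable_for_survival(self) -> pd.Series:
        """Boolean mask of rows with non-missing time and event."""
        return self.data["time"].notna() & self.data["event"].notna()

    def survival_frame(self) -> pd.DataFrame:
        """Rows usable for survival analysis, with numeric time/event."""
        frame = self.data.loc[self.usable_for_survival].copy()
        frame["time"] = frame["time"].astype(float)
        frame["event"] = frame["event"].astype(int)
        return frame


@dataclass
class SignatureScoreVector:
    """Per-sample signature scores plus bookkeeping on gene matching."""

    scores: pd.Series  # index: sample ids
    matched_genes: int
    missing_genes: list = field(default_factory=list)
    standardized: bool = False
    signature_name: str = "signature"

    def __post_init__(self):
        if not isinstance(self.scores, pd.Series):
            self.scores = pd.Series(self.scores)
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("signature scores must be finite")
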