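"""Synthetic cohorts with the joint structure the pipeline assumes.

A latent binary pathway activation a_j ~ Bernoulli(prevalence) drives three
observables per sample j:

* the phosphoprotein readout:  protein_j = protein_effect * a_j + N(0, noise_sd)
* the planted signature genes: e_ij = s_i * effect_size * a_j + N(0, noise_sd)
  with signs s_i alternating +1, -1, ... (both directions exercised);
  non-signature genes are pure noise
* the survival hazard: exponential proportional hazards with linear
  predictor  log_hr_treatment * T_j + log_hr_activation * a_j +
  log_hr_interaction * T_j * a_j,  with independent uniform censoring whose
  horizon is calibrated by bisection to the target censoring fraction.

One global seed is split into per-component streams (activation, protein,
expression, clinical, survival, censoring) so e.g. adding genes does not
perturb the survival draws.  The same config and seed always produce a
byte-identical cohort.

Clinical covariates (age, tumor size, grade, nodal status, ER status) are
drawn independently of activation, mirroring the absence of association
between phosphoprotein status and classic clinicopathological features in
the kind of cohort emulated.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, GeneSignature
from .exceptions import ValidationError

_STREAMS = ("activation", "protein", "expression", "clinical", "survival", "censoring")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic cohort.

    Effect sizes are in units of ``noise_sd``; hazards are per month.
    """

    n_samples: int = 100
    n_genes: int = 1000
    n_signature_genes: int = 50
    effect_size: float = 1.5
    protein_effect: float = 2.0
    activation_prevalence: float = 0.5
    noise_sd: float = 1.0
    baseline_hazard: float = 0.02
    log_hr_treatment: float = -0.4
    log_hr_activation: float = 0.3
    log_hr_interaction: float = 0.8
    censoring_rate_target: float = 0.3
    treatment_fraction: float = 0.5
    er_neg_fraction: float = 0.4
    seed: int = 0
    #: sample-id prefix; defaults to the seed so cohorts drawn with
    #: different seeds have disjoint sample ids (transfer-validation guard)
    sample_prefix: str = ""

    def __post_init__(self):
        if self.n_signature_genes > self.n_genes:
            raise ValidationError("n_signature_genes must be <= n_genes")
        if self.n_samples < 1 or self.n_genes < 1 or self.n_signature_genes < 0:
            raise ValidationError("sizes must be positive (n_signature_genes >= 0)")
        if not 0 < self.activation_prevalence < 1:
            raise ValidationError("activation_prevalence must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        if not 0 <= self.censoring_rate_target <= 0.99:
            raise ValidationError(
                "censoring_rate_target must lie in [0, 0.99]; higher targets are infeasible"
            )
        if not 0 < self.treatment_fraction < 1:
            raise ValidationError("treatment_fraction must lie in (0, 1)")
        if not 0 <= self.er_neg_fraction <= 1:
            raise ValidationError("er_neg_fraction must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Matched expression, protein and clinical data with known ground truth."""

    expression: ExpressionMatrix
    protein: pd.Series
    clinical: ClinicalTable
    truth_signature: GeneSignature
    truth_activation: pd.Series
    config: SimulationConfig

    def __post_init__(self):
        ids = list(self.expression.sample_ids)
        for other in (list(self.protein.index), self.clinical.sample_ids,
                      list(self.truth_activation.index)):
            if other != ids:
                raise ValidationError("cohort components must share identical sample ids")
        missing = set(self.truth_signature.genes) - set(self.expression.gene_ids)
        if missing:
            raise ValidationError(f"truth signature genes not in matrix: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list:
        return self.expression.sample_ids

    def serialize(self) -> bytes:
        """Canonical byte serialization (used for determinism checks)."""
        buf = _io.StringIO()
        self.expression.data.to_csv(buf, sep="\t", float_format="%.12g")
        self.protein.to_csv(buf, sep="\t", float_format="%.12g")
        self.clinical.data.to_csv(buf, float_format="%.12g")
        self.truth_activation.to_csv(buf, sep="\t")
        buf.write(json.dumps(asdict(self.config), sort_keys=True))
        buf.write(json.dumps(self.truth_signature.entries.__repr__()))
        return buf.getvalue().encode("utf-8")

    def checksum(self) -> str:
        return hashlib.sha256(self.serialize()).hexdigest()

    def write(self, out_dir) -> dict:
        """Write expression TSV, protein TSV, clinical CSV, truth signature
        TSV and a config echo; returns the path map."""
        from . import io as pio  # local import to avoid cycle at module load
        import yaml

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out / "expression.tsv",
            "protein": out / "protein.tsv",
            "clinical": out / "clinical.csv",
            "truth_signature": out / "truth_signature.tsv",
            "truth_activation": out / "truth_activation.tsv",
            "config": out / "config.yaml",
        }
        pio.write_expression_matrix(self.expression, paths["expression"])
        pio.write_protein_values(self.protein, paths["protein"])
        pio.write_clinical_table(self.clinical, paths["clinical"])
        pio.write_signature(self.truth_signature, paths["truth_signature"])
        with open(paths["truth_activation"], "wt", encoding="utf-8", newline="\n") as fh:
            self.truth_activation.rename("activation").to_csv(fh, sep="\t", index_label="sample_id")
        with open(paths["config"], "wt", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=True)
        return {k: str(v) for k, v in paths.items()}


def _calibrate_censoring_horizon(event_times: np.ndarray, u: np.ndarray, target: float) -> float:
    """Bisect the uniform-censoring horizon C so that the realized fraction
    of subjects with C*u < T matches the target censoring rate."""
    def censored_fraction(c):
        return float(np.mean(c * u < event_times))

    lo, hi = 1e-12, float(np.max(event_times)) / max(np.min(u), 1e-12) + 1.0
    while censored_fraction(hi) > target:
        hi *= 2.0
        if hi > 1e300:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) > target:
            lo = mid
        else:
            hi = mid
    return hi


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort from the generative model described in the module docs."""
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            _STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
        )
    }
    n, g, k = config.n_samples, config.n_genes, config.n_signature_genes
    prefix = config.sample_prefix or str(config.seed)
    samples = [f"S{prefix}-{j:04d}" for j in range(n)]
    genes = [f"G{i:05d}" for i in range(g)]

    activation = streams["activation"].binomial(1, config.activation_prevalence, n)
    protein = config.protein_effect * activation + streams["protein"].normal(
        0.0, config.noise_sd, n
    )

    signs = np.array([1 if i % 2 == 0 else -1 for i in range(k)], dtype=int)
    expr = streams["expression"].normal(0.0, config.noise_sd, (g, n))
    if k:
        expr[:k] += signs[:, None] * config.effect_size * activation[None, :]
    expression = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    truth_signature = GeneSignature(
        tuple(zip(genes[:k], signs.tolist())),
        name="truth" if config.effect_size != 0 else "null",
    )

    rng_c = streams["clinical"]
    treatment = rng_c.binomial(1, config.treatment_fraction, n)
    er_status = np.where(
        rng_c.random(n) < config.er_neg_fraction, "neg", "pos"
    )
    age = np.round(rng_c.normal(55.0, 10.0, n), 1)
    tumor_size = np.round(rng_c.lognormal(np.log(2.0), 0.4, n), 2)  # cm
    grade = rng_c.choice([1, 2, 3], size=n, p=[0.2, 0.5, 0.3])
    nodal_status = rng_c.binomial(1, 0.5, n)

    lp = (
        config.log_hr_treatment * treatment
        + config.log_hr_activation * activation
        + config.log_hr_interaction * treatment * activation
    )
    rate = config.baseline_hazard * np.exp(lp)
    event_times = streams["survival"].exponential(1.0 / rate)

    if config.censoring_rate_target > 0:
        u = streams["censoring"].random(n)
        horizon = _calibrate_censoring_horizon(event_times, u, config.censoring_rate_target)
        censor_times = horizon * u
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time, event = event_times, np.ones(n, dtype=int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "treatment": treatment,
                "er_status": er_status,
                "age": age,
                "tumor_size": tumor_size,
                "grade": grade,
                "nodal_status": nodal_status,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return SyntheticCohort(
        expression=expression,
        protein=pd.Series(protein, index=samples, name="protein"),
        clinical=clinical,
        truth_signature=truth_signature,
        truth_activation=pd.Series(activation, index=samples, name="activation"),
        config=config,
    )


def simulate_null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Cohort from the null generative model: no expression signal, no
    protein signal, no treatment interaction."""
    null_config = replace(
        config, effect_size=0.0, protein_effect=0.0, log_hr_interaction=0.0
    )
    return simulate_cohort(null_config)
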