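"""End-to-end orchestration: simulate/load -> group -> derive -> score ->
validate -> survive -> associate, with a reproducibility manifest.

Every stage writes its output in the plain-text formats of the module that
owns it, so any stage can be re-run standalone.  The manifest records the
package version, a hash of the canonical config, hashes of all input files
and per-stage counts; two runs of the same config differ only in the
manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .datatypes import ClinicalTable, ExpressionMatrix, GeneSignature
from .derive import derive_signature
from .exceptions import PipelineStageError, ValidationError
from .grouping import group_samples, sd_groups
from .scoring import dichotomize_scores, score_samples
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort
from .survival import interaction_lrt, log_rank
from .validate import pearson_correlation, roc_auc
from .association import correlation_screen

logger = logging.getLogger(__name__)


@dataclass
class Cohort:
    """A loaded (or simulated) cohort: expression + protein (+ clinical)."""

    expression: ExpressionMatrix
    protein: pd.Series
    clinical: Optional[ClinicalTable] = None

    @property
    def sample_ids(self) -> list:
        return self.expression.sample_ids


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run.

    Either ``simulate`` (generative parameters) or ``inputs`` (paths to
    expression TSV, protein TSV, clinical CSV) must be given.
    """

    simulate: Optional[dict] = None
    inputs: Optional[dict] = None
    grouping: dict = field(default_factory=lambda: {"method": "quartile"})
    derivation: dict = field(default_factory=lambda: {"fdr": 0.05, "mode": "robust"})
    scoring: dict = field(default_factory=dict)
    dichotomization: dict = field(default_factory=lambda: {"method": "median"})
    validation: dict = field(default_factory=lambda: {"truth_method": "sd", "k": 1.0})
    survival: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        """Validation-first contract: fail before any stage runs."""
        if (self.simulate is None) == (self.inputs is None):
            raise ValidationError("exactly one of 'simulate' or 'inputs' must be set")
        if self.inputs is not None:
            for key in ("expression", "protein"):
                if key not in self.inputs:
                    raise ValidationError(f"inputs must include '{key}'")
            for key, path in self.inputs.items():
                if not Path(path).is_file():
                    raise ValidationError(f"input file for '{key}' not found: {path}")
        fdr = self.derivation.get("fdr")
        if fdr is not None and not 0 < fdr <= 1:
            raise ValidationError("derivation fdr must lie in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_cohort(config: PipelineConfig, out_dir: Path, manifest: dict) -> Cohort:
    if config.simulate is not None:
        sim_params = dict(config.simulate)
        sim_params.setdefault("seed", config.seed)
        sim_config = SimulationConfig(**sim_params)
        cohort = simulate_cohort(sim_config)
        paths = cohort.write(out_dir / "simulated")
        manifest["inputs"] = {k: _sha256(v) for k, v in paths.items()}
        return Cohort(cohort.expression, cohort.protein, cohort.clinical)
    inputs = config.inputs
    manifest["inputs"] = {k: _sha256(v) for k, v in inputs.items()}
    expression = pio.read_expression_matrix(
        inputs["expression"], format=inputs.get("format", "tsv")
    )
    if "probe_map" in inputs:
        expression = pio.collapse_probes_to_genes(
            expression, pio.read_probe_map(inputs["probe_map"])
        )
    protein = pio.read_protein_values(inputs["protein"])
    clinical = (
        pio.read_clinical_table(inputs["clinical"]) if "clinical" in inputs else None
    )
    return Cohort(expression, protein, clinical)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full workflow; returns the manifest dict.

    Artifacts written to ``out_dir``: labels.tsv, sig.tsv, de.tsv,
    scores.tsv, roc.json, report.json, manifest.json (plus simulated/ when
    the cohort is generated).  A stage failure raises
    :class:`PipelineStageError` naming the stage; earlier artifacts are
    preserved.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "protsig",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
    }
    report: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:  # preserve partial outputs, name the stage
                _finish(manifest, out, failed=name)
                raise PipelineStageError(name, str(exc)) from exc
            logger.info("stage %s: %s", name, manifest["stages"].get(name, {}))
            return result
        return wrap

    cohort = stage("load")(lambda: _load_cohort(config, out, manifest))

    def _group():
        params = dict(config.grouping)
        method = params.pop("method", "quartile")
        labels = group_samples(cohort.protein, method=method, **params)
        labels.labels.rename("label").to_csv(out / "labels.tsv", sep="\t", index_label="sample_id")
        manifest["stages"]["group"] = {
            "method": method, "n_high": labels.n_high, "n_low": labels.n_low,
        }
        return labels

    labels = stage("group")(_group)

    def _derive():
        params = dict(config.derivation)
        sig, table = derive_signature(
            cohort.expression,
            labels,
            fdr_threshold=params.get("fdr", 0.05),
            p_threshold=params.get("p"),
            fold_threshold=params.get("fold"),
            mode=params.get("mode", "robust"),
        )
        pio.write_signature(sig, out / "sig.tsv")
        table.to_csv(out / "de.tsv", sep="\t", float_format="%.10g")
        manifest["stages"]["derive"] = {
            "genes_tested": int(len(table)), "genes_selected": len(sig),
        }
        return sig

    signature = stage("derive")(_derive)
    if len(signature) == 0:
        report["status"] = "not_applicable"
        report["reason"] = "empty signature: no gene passed the derivation thresholds"
        _write_report(report, out)
        _finish(manifest, out)
        return manifest
    report["status"] = "ok"
    report["signature_size"] = len(signature)

    def _score():
        scores = score_samples(
            cohort.expression,
            signature,
            standardize=config.scoring.get("standardize", False),
            scale_by_n=config.scoring.get("scale_by_n", False),
        )
        frame = scores.scores.rename("score").to_frame()
        frame["matched_genes"] = scores.matched_genes
        frame.to_csv(out / "scores.tsv", sep="\t", float_format="%.10g", index_label="sample_id")
        manifest["stages"]["score"] = {
            "samples_scored": int(len(scores.scores)),
            "matched_genes": scores.matched_genes,
        }
        return scores

    scores = stage("score")(_score)

    def _validate():
        r, p = pearson_correlation(
            scores.scores.to_numpy(), cohort.protein.reindex(scores.scores.index).to_numpy()
        )
        truth = sd_groups(cohort.protein, k=config.validation.get("k", 1.0))
        roc = roc_auc(scores, truth)
        payload = roc.to_dict()
        payload.update({"pearson_r": r, "pearson_p": p})
        with open(out / "roc.json", "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        manifest["stages"]["validate"] = {"auc": roc.auc, "pearson_r": r}
        report["validation"] = {"auc": roc.auc, "auc_p": roc.p_value, "pearson_r": r, "pearson_p": p}

    stage("validate")(_validate)

    def _survive():
        if cohort.clinical is None:
            manifest["stages"]["survive"] = {"skipped": "no clinical table"}
            return
        frame = cohort.clinical.survival_frame()
        common = frame.index.intersection(scores.scores.index)
        frame = frame.loc[common]
        stratify = config.survival.get("stratify")
        strat_series = frame[stratify] if stratify else None
        groups = dichotomize_scores(
            type(scores)(scores.scores.loc[common], scores.matched_genes,
                         scores.missing_genes, scores.standardized),
            stratify_by=strat_series,
        )
        lr = log_rank(frame["time"], frame["event"], (groups == "high").astype(int))
        surv_report = {
            "n": int(len(frame)),
            "n_events": int(frame["event"].sum()),
            "log_rank_chi2": lr.chi_square,
            "log_rank_p": lr.p_value,
        }
        if "treatment" in frame.columns and frame["treatment"].nunique() == 2:
            covariate_names = config.survival.get("covariates", [])
            covs = None
            if covariate_names:
                covs = frame[list(covariate_names)].copy()
                if "er_status" in covs.columns:
                    covs["er_status"] = (covs["er_status"] == "pos").astype(float)
                covs = covs.astype(float)
            stat, p, full, reduced = interaction_lrt(
                frame["time"], frame["event"],
                scores.scores.loc[common].to_numpy(), frame["treatment"].to_numpy(),
                covariates=covs,
            )
            surv_report["interaction_lrt"] = stat
            surv_report["interaction_p"] = p
            surv_report["cox_full"] = json.loads(full.summary().to_json(orient="index"))
        manifest["stages"]["survive"] = {
            "n": surv_report["n"], "events": surv_report["n_events"],
        }
        report["survival"] = surv_report

    stage("survive")(_survive)

    def _associate():
        features_path = config.association.get("features")
        if not features_path:
            manifest["stages"]["associate"] = {"skipped": "no feature panel"}
            return
        features = pd.read_csv(features_path, sep="\t", index_col=0)
        table = correlation_screen(scores.scores, features)
        table.to_csv(out / "corr.tsv", sep="\t", float_format="%.10g")
        manifest["stages"]["associate"] = {"features_tested": int(len(table))}

    stage("associate")(_associate)

    _write_report(report, out)
    _finish(manifest, out)
    return manifest


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "wt", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=float)


def _finish(manifest: dict, out: Path, failed: Optional[str] = None) -> None:
    if failed:
        manifest["failed_stage"] = failed
    manifest["timestamp"] = _time.strftime("%Y-%m-%dT%H:%M:%S%z")
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=float)


def run_transfer_validation(
    train: Cohort | SyntheticCohort,
    test: Cohort | SyntheticCohort,
    grouping: Optional[dict] = None,
    derivation: Optional[dict] = None,
    truth_k: float = 1.0,
) -> dict:
    """Derive a signature on ``train`` only and evaluate it on ``test``.

    The two cohorts must have disjoint sample ids (leakage guard).  Returns
    a report with the training-set score-protein correlation and the
    test-set AUC against mean +/- k*SD protein truth labels; when the
    derived signature is empty the report is marked ``not_applicable``.
    """
    overlap = set(train.expression.sample_ids) & set(test.expression.sample_ids)
    if overlap:
        raise ValidationError(
            f"train/test sample ids overlap (leakage): {sorted(overlap)[:5]}"
        )
    grouping = dict(grouping or {"method": "quartile"})
    derivation = dict(derivation or {})
    labels = group_samples(train.protein, method=grouping.pop("method", "quartile"), **grouping)
    signature, table = derive_signature(
        train.expression,
        labels,
        fdr_threshold=derivation.get("fdr", 0.05),
        p_threshold=derivation.get("p"),
        fold_threshold=derivation.get("fold"),
        mode=derivation.get("mode", "robust"),
    )
    report = {"signature_size": len(signature), "genes_tested": int(len(table))}
    if len(signature) == 0:
        report["status"] = "not_applicable"
        report["reason"] = "empty signature derived on the training cohort"
        return report
    report["status"] = "ok"
    train_scores = score_samples(train.expression, signature)
    r, p = pearson_correlation(
        train_scores.scores.to_numpy(),
        train.protein.reindex(train_scores.scores.index).to_numpy(),
    )
    report["train_pearson_r"] = r
    report["train_pearson_p"] = p
    test_scores = score_samples(test.expression, signature)
    truth = sd_groups(test.protein, k=truth_k)
    roc = roc_auc(test_scores, truth)
    report["test_auc"] = roc.auc
    report["test_auc_p"] = roc.p_value
    report["test_n_pos"] = roc.n_pos
    report["test_n_neg"] = roc.n_neg
    return report
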