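"""End-to-end pipeline: QC -> phenotype -> screen -> sweep -> select -> dedup
-> validate -> score.

Each stage's artifact can be written to an output directory, and a
machine-readable manifest records every threshold, every seed and every
stage count, plus a deterministic content hash, so a run can be
reconstructed (and audited) from its manifest alone.

A cohort with no significant model is a first-class outcome: the pipeline
returns status ``"no_model"`` instead of raising.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, QCReport
from .io import PipelineConfig, write_dosage_tsv
from .phenotype import cohort_phenotype, covariate_screen, paired_meal_tests, percent_cv
from .qc import run_qc
from .score import GeneticScoreModel, score_from_fit
from .screen import AssociationResult, design_matrix, screen_all
from .selection import (
    FinalModel,
    SelectionTrace,
    ld_dedup_selected,
    select_model,
    vip_sweep,
)
from .validation import (
    ValidationReport,
    coefficient_stability,
    cv_anova,
    leave_k_out,
    permutation_validation,
)

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("tocopls")


@dataclass
class PipelineResult:
    status: str                                   # "ok" | "no_model"
    config: PipelineConfig
    qc_matrix: GenotypeMatrix
    qc_report: QCReport
    phenotype: pd.DataFrame                       # per-participant aggregate
    covariates_kept: list[str]
    covariate_table: pd.DataFrame
    screen_results: list[AssociationResult]
    screen_retained: list[AssociationResult]
    trace: SelectionTrace | None = None
    final: FinalModel | None = None
    validation: ValidationReport | None = None
    score_model: GeneticScoreModel | None = None
    covariate_coefficients: dict[str, float] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def coefficient_table(self) -> pd.DataFrame:
        """Final-model coefficients shaped like a published SNP table."""
        if self.score_model is None:
            return pd.DataFrame(columns=["gene", "snp_id", "coding", "vip",
                                         "coefficient"])
        annotation = self.qc_matrix.annotation
        rows = []
        for e in self.score_model.entries:
            gene = e.gene
            if not gene and annotation is not None and e.snp_id in annotation.index:
                gene = str(annotation.loc[e.snp_id, "gene"])
            rows.append({"gene": gene, "snp_id": e.snp_id, "coding": e.coding,
                         "vip": e.vip, "coefficient": e.coefficient})
        return pd.DataFrame(rows)


def _manifest_hash(manifest: dict) -> str:
    payload = json.dumps(manifest, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(
    genotypes: GenotypeMatrix,
    measurements: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole two-step association analysis on one cohort."""
    config = config or PipelineConfig()
    config.validate()
    seed = config.seed

    # 1. genotype QC
    g_qc, report = run_qc(
        genotypes,
        call_rate_min=config.call_rate_min,
        hwe_alpha=config.hwe_alpha,
        ld_r2=config.ld_r2,
        seed=seed,
    )
    for stage in report.stages:
        logger.info("QC %s: %d in, %d excluded, %d out",
                    stage.name, stage.n_in, stage.n_excluded, stage.n_out)

    # 2. phenotype aggregation (replicates -> one value per participant)
    pheno = cohort_phenotype(measurements, config.grubbs_alpha)
    pheno = pheno.reindex(g_qc.participant_ids)
    if pheno["atoc"].isna().any():
        missing = list(pheno.index[pheno["atoc"].isna()])
        raise ValueError(f"no phenotype for participants {missing}")
    y = pheno["atoc"]
    meal_tests = paired_meal_tests(measurements)

    # 3. covariate screen (CI excluding zero)
    kept_cov: list[str] = []
    cov_table = pd.DataFrame()
    if covariates is not None and len(covariates.columns):
        kept_cov, cov_table = covariate_screen(y, covariates, config.ci_level)
    logger.info("covariate screen kept %s", kept_cov or "none")

    # 4. univariate SNP screen
    tested, retained = screen_all(g_qc, y, config.screen_alpha, config.min_group)
    logger.info("univariate screen: %d tests, %d retained", len(tested),
                len(retained))

    manifest = {
        "config": {
            "call_rate_min": config.call_rate_min,
            "hwe_alpha": config.hwe_alpha,
            "ld_r2": config.ld_r2,
            "min_group": config.min_group,
            "screen_alpha": config.screen_alpha,
            "ci_level": config.ci_level,
            "vip_grid": list(config.vip_grid),
            "cv_folds": config.cv_folds,
            "n_perm": config.n_perm,
            "grubbs_alpha": config.grubbs_alpha,
            "seed": seed,
        },
        "qc": report.to_frame().to_dict(orient="records"),
        "n_participants": g_qc.n_participants,
        "phenotype_cv_percent": percent_cv(y.to_numpy()),
        "meal_tests": {k: v.p for k, v in meal_tests.items()},
        "covariates_kept": kept_cov,
        "screen": {"tested": len(tested), "retained": len(retained)},
    }

    result = PipelineResult(
        status="no_model",
        config=config,
        qc_matrix=g_qc,
        qc_report=report,
        phenotype=pheno,
        covariates_kept=kept_cov,
        covariate_table=cov_table,
        screen_results=tested,
        screen_retained=retained,
        manifest=manifest,
    )

    if not retained and not kept_cov:
        logger.info("nothing retained by screening: no model")
        manifest["status"] = "no_model"
        manifest["hash"] = _manifest_hash(manifest)
        _write_artifacts(result, out_dir)
        return result

    # 5. multivariate design and VIP sweep
    X, var_map = design_matrix(g_qc, retained, covariates, kept_cov)
    trace = vip_sweep(X, y.to_numpy(), thresholds=config.vip_thresholds(),
                      folds=config.cv_folds, seed=seed)
    result.trace = trace
    manifest["sweep"] = trace.to_frame().drop(columns="variables").to_dict(
        orient="records"
    )

    # 6. model selection + post-selection LD dedup
    chosen = select_model(trace, config.screen_alpha)
    if chosen is None:
        logger.info("no sweep entry significant by CV-ANOVA: no model")
        manifest["status"] = "no_model"
        manifest["hash"] = _manifest_hash(manifest)
        _write_artifacts(result, out_dir)
        return result
    final = ld_dedup_selected(chosen, X, y.to_numpy(), g_qc, var_map,
                              r2_threshold=config.ld_r2,
                              folds=config.cv_folds, seed=seed)
    result.final = final
    logger.info("selected %d variables (threshold %.2f), %d after LD dedup",
                chosen.k, chosen.threshold, final.k)

    # 7. validation battery
    Xf = X[list(final.variables)]
    validation = ValidationReport(
        cv_anova=final.cv_anova,
        permutation=permutation_validation(Xf, y.to_numpy(), A=final.model.A,
                                           n_perm=config.n_perm, seed=seed,
                                           folds=config.cv_folds),
        leave_k_out=leave_k_out(Xf, y.to_numpy(), final.model.A,
                                ks=[k for k in config.leave_k_out_ks
                                    if k < len(y)],
                                seed=seed),
        stability=coefficient_stability(Xf, y.to_numpy(), final.model.A,
                                        folds=config.cv_folds, seed=seed),
    )
    result.validation = validation

    # 8. genetic score export
    score_model, cov_part = score_from_fit(final.model, var_map)
    result.score_model = score_model
    result.covariate_coefficients = cov_part
    result.status = "ok"

    manifest["status"] = "ok"
    manifest["final"] = {
        "variables": list(final.variables),
        "dropped_ld": list(final.dropped_ld),
        "A": final.model.A,
        "r2": final.r2,
        "adj_r2": final.adj_r2,
        "q2": final.q2,
        "cv_anova_p": final.cv_anova.p,
        "intercept": score_model.intercept,
    }
    manifest["validation"] = validation.to_dict()
    manifest["hash"] = _manifest_hash(manifest)
    result.manifest = manifest
    _write_artifacts(result, out_dir)
    return result


def _write_artifacts(result: PipelineResult, out_dir: str | Path | None) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dosage_tsv(result.qc_matrix, out / "genotypes_qc.tsv")
    result.qc_report.to_frame().to_csv(out / "qc_stages.tsv", sep="\t", index=False)
    result.qc_report.exclusions_frame().to_csv(out / "qc_exclusions.tsv",
                                               sep="\t", index=False)
    result.phenotype.to_csv(out / "phenotype.tsv", sep="\t")
    screen_frame = pd.DataFrame(
        [
            {"snp_id": r.snp_id, "coding": r.coding, "beta": r.beta, "se": r.se,
             "p": r.p, "n": r.n,
             "groups": "/".join(str(c) for c in r.group_counts)}
            for r in result.screen_results
        ]
    )
    screen_frame.to_csv(out / "screen.tsv", sep="\t", index=False)
    if result.trace is not None:
        result.trace.to_frame().to_csv(out / "sweep.tsv", sep="\t", index=False)
    if result.score_model is not None:
        result.score_model.save(out / "score_model.json")
        result.coefficient_table().to_csv(out / "final_coefficients.tsv",
                                          sep="\t", index=False)
    if result.validation is not None:
        (out / "validation.json").write_text(
            json.dumps(result.validation.to_dict(), indent=1, default=float)
        )
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True, default=str)
    )
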