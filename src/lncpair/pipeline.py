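"""End-to-end orchestration: screen -> pair -> fit -> evaluate -> associate.

A single global seed is fanned out to per-stage child seeds by fixed
offsets, so each stage is individually reproducible.  The run report
records the selection funnel (lncRNAs -> irlncRNAs -> DEirlncRNAs ->
pairs built -> stable pairs -> pairs past the univariate screen ->
pairs past LASSO -> final signature size) together with the headline
evaluation results.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, evaluation, io, pairing, screening, signature

logger = logging.getLogger("lncpair")

# fixed per-stage seed offsets
SEED_LASSO = 11


@dataclass
class PipelineConfig:
    """Thresholds, horizons and the seed of one pipeline run."""

    r_min: float = 0.8
    p_adj_max: float = 0.001
    logfc_min: float = 1.0
    fdr_max: float = 0.05
    stability_low: float = 0.2
    stability_high: float = 0.8
    alpha: float = 0.05
    n_folds: int = 10
    horizons: tuple[float, ...] = (365.0, 730.0, 1095.0)
    cutoff_method: str = "aic"
    checkpoints: tuple[str, ...] = association.DEFAULT_CHECKPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.stability_low < self.stability_high <= 1:
            raise ValueError("require 0 <= stability_low < stability_high <= 1")
        for name in ("r_min", "p_adj_max", "logfc_min", "fdr_max", "alpha"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.r_min <= 1:
            raise ValueError("r_min must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.cutoff_method not in ("aic", "youden"):
            raise ValueError("cutoff_method must be 'aic' or 'youden'")
        if not self.horizons:
            raise ValueError("need at least one evaluation horizon")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for key in ("horizons", "checkpoints"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    report: dict
    signature_table: pd.DataFrame
    risk: "signature.RiskProfile"
    pair_matrix: pairing.PairMatrix
    de_table: pd.DataFrame
    rocs: dict[float, evaluation.TimedROC]
    km: evaluation.KMResult
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = _time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, _time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(expression: io.ExpressionMatrix,
                 annotation: pd.Series,
                 immune_list,
                 clinical: pd.DataFrame,
                 config: PipelineConfig | None = None,
                 infiltration: pd.DataFrame | None = None,
                 checkpoint_expr: pd.DataFrame | None = None,
                 drug_scores: pd.Series | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis and return the report plus all artifacts."""
    cfg = config or PipelineConfig()
    report: dict = {"config": asdict(cfg)}
    report["n_features"] = len(expression.feature_ids)
    report["n_tumor"] = len(expression.tumor_samples)
    report["n_normal"] = len(expression.normal_samples)

    lnc_expr, irg_expr = _stage("split")(io.split_by_biotype)(
        expression, annotation, immune_list)
    report["n_lnc"] = len(lnc_expr.feature_ids)
    report["n_irgene"] = len(irg_expr.feature_ids)

    irlnc, hits = _stage("screen:correlation")(screening.correlate_immune)(
        lnc_expr, irg_expr, r_min=cfg.r_min, p_adj_max=cfg.p_adj_max)
    report["n_irlnc"] = len(irlnc)

    de_table = _stage("screen:de")(screening.differential_expression)(
        lnc_expr.subset(features=irlnc), logfc_min=cfg.logfc_min,
        fdr_max=cfg.fdr_max)
    de_ids = list(de_table.loc[de_table["de"], "lnc_id"])
    report["n_de"] = len(de_ids)
    report["n_de_up"] = int((de_table["de"] & (de_table["direction"] == "up")).sum())
    report["n_de_down"] = int((de_table["de"] & (de_table["direction"] == "down")).sum())

    surv = io.survival_cohort(clinical)
    cohort_samples = [s for s in expression.tumor_samples if s in surv.index]
    report["n_survival_cohort"] = len(cohort_samples)

    pm_all = _stage("pair:build")(pairing.build_pair_matrix)(
        lnc_expr.subset(features=de_ids, samples=cohort_samples))
    report["n_pairs_built"] = len(pm_all.pair_ids)
    pm = _stage("pair:stability")(pairing.filter_stable_pairs)(
        pm_all, low=cfg.stability_low, high=cfg.stability_high)
    report["n_pairs_stable"] = len(pm.pair_ids)

    uni = _stage("fit:unicox")(signature.unicox_screen)(pm, surv, alpha=cfg.alpha)
    report["n_pairs_unicox"] = len(uni)

    retained = pm.subset(list(uni["pair_id"]))
    if len(uni) >= 2:
        selected = _stage("fit:lasso")(signature.lasso_cox_select)(
            retained, surv, n_folds=cfg.n_folds, seed=cfg.seed + SEED_LASSO)
    else:
        selected = list(uni["pair_id"])
    report["n_pairs_lasso"] = len(selected)

    model, sig_table = _stage("fit:stepwise")(signature.stepwise_multicox)(
        selected, retained, surv)
    report["n_final"] = model.n_pairs
    report["final_pairs"] = list(model.pairs)

    risk = _stage("fit:score")(signature.compute_risk_scores)(model, pm)

    rocs = {}
    for h in cfg.horizons:
        rocs[h] = _stage(f"evaluate:roc@{h:g}")(evaluation.timed_roc)(
            risk.scores, surv, h)
    report["auc"] = {f"{h:g}": rocs[h].auc for h in cfg.horizons}

    first_h = cfg.horizons[0]
    cut = _stage("evaluate:cutoff")(evaluation.find_cutoff)(
        rocs[first_h], risk.scores, surv, method=cfg.cutoff_method)
    report["cutoff"] = {"value": cut.cutoff, "method": cut.method,
                        "criterion": cut.criterion_value,
                        "unstable": cut.unstable}
    risk = evaluation.assign_groups(risk.scores, cut.cutoff)
    report["n_high"] = int((risk.groups == "high").sum())
    report["n_low"] = int((risk.groups == "low").sum())

    km = _stage("evaluate:km")(evaluation.km_logrank)(risk.groups, surv)
    report["logrank"] = {"statistic": km.statistic, "p": km.p}

    roc_cmp = _stage("evaluate:comparators")(evaluation.clinical_roc_comparison)(
        risk.scores, surv, first_h)

    tables: dict[str, pd.DataFrame] = {"roc_comparators": roc_cmp}
    clin_vars = [v for v in ("gender", "grade", "stage", "t_stage",
                             "n_stage", "m_stage") if v in surv.columns]
    if clin_vars:
        assoc, summary = _stage("associate:chisq")(association.chisq_clinical)(
            risk.groups, surv, clin_vars)
        tables["clinical_assoc"] = assoc
        tables["clinical_summary"] = summary
        sub_rows = []
        for var in [v for v in association.SUBGROUP_RULES if v in surv.columns]:
            try:
                sub_rows.append(_stage(f"associate:ranksum:{var}")(
                    association.ranksum_by_subgroup)(risk.scores, surv, var))
            except PipelineError as err:
                logger.warning("ranksum for %s skipped: %s", var, err.cause)
        tables["score_subgroups"] = pd.DataFrame(sub_rows)
        tables["cox_independence"] = _stage("associate:independence")(
            association.cox_independence)(risk.scores, surv)
        tables["subgroup_logrank"] = _stage("associate:subgroup-km")(
            association.subgroup_survival)(risk.groups, surv)
    if any(t is not None for t in (infiltration, checkpoint_expr, drug_scores)):
        tables["immune_drug"] = _stage("associate:immune-drug")(
            association.immune_drug_correlations)(
                risk.scores, risk.groups, infiltration, checkpoint_expr,
                drug_scores)

    result = PipelineResult(report=report, signature_table=sig_table,
                            risk=risk, pair_matrix=pm, de_table=de_table,
                            rocs=rocs, km=km, tables=tables)
    if outdir is not None:
        _write_outputs(result, hits, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, hits: pd.DataFrame, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    hits.to_csv(outdir / "irlncRNA_hits.tsv", sep="\t", index=False)
    result.de_table.to_csv(outdir / "DEirlncRNA.tsv", sep="\t", index=False)
    result.pair_matrix.write(outdir / "pair_matrix.tsv")
    result.signature_table.to_csv(outdir / "signature.tsv", sep="\t", index=False)
    result.risk.scores.rename("risk_score").to_frame().rename_axis(
        "sample_id").to_csv(outdir / "risk_scores.tsv", sep="\t")
    if result.risk.groups is not None:
        result.risk.groups.rename("risk_group").to_frame().rename_axis(
            "sample_id").to_csv(outdir / "groups.tsv", sep="\t")
    for h, roc in result.rocs.items():
        pd.DataFrame({"threshold": roc.thresholds, "sens": roc.sens,
                      "spec": roc.spec}).to_csv(
            outdir / f"roc_{h:g}.tsv", sep="\t", index=False)
    with open(outdir / "cutoff.json", "w") as fh:
        json.dump(result.report["cutoff"], fh, indent=2, sort_keys=True)
    for lab, curve in result.km.curves.items():
        curve.to_csv(outdir / f"km_{lab}.tsv", sep="\t", index=False)
    for name, tab in result.tables.items():
        tab.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, default=str)


def run_pipeline_on_cohort(cohort, config: PipelineConfig | None = None,
                           outdir=None) -> PipelineResult:
    """Convenience wrapper running the pipeline on a synthetic cohort."""
    return run_pipeline(
        expression=cohort.expression,
        annotation=cohort.annotation,
        immune_list=cohort.immune_genes,
        clinical=cohort.clinical,
        config=config,
        infiltration=cohort.infiltration,
        checkpoint_expr=cohort.checkpoints,
        drug_scores=cohort.drug_scores,
        outdir=outdir,
    )
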