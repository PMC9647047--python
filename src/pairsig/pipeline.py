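"""End-to-end orchestration: simulate → encode → screen → select → score → evaluate.

The build funnel mirrors the signature-construction recipe: variability
screen on genes, exhaustive single pairing into a 0-or-1 matrix, prevalence
filter, univariate Cox screen (p < alpha), repeated cross-validated
LASSO-Cox selection, and an unpenalized multivariate Cox refit that supplies
the signature coefficients.  Stage-by-stage counts are logged and returned.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pairsig import __version__, io
from pairsig.cohort import SimulationConfig, export_cohort, generate_cohort
from pairsig.errors import ConfigError, InputError, StageAbortError
from pairsig.evaluation import (
    DEFAULT_HORIZONS,
    association_suite,
    clinical_cox,
    correlation,
    time_dependent_roc,
    tmb,
    youden_cutoff,
)
from pairsig.pairs import (
    build_pair_matrix,
    intersect_available_genes,
    mad_filter,
    prevalence_filter,
)
from pairsig.signature import (
    RiskScoreTable,
    SignatureModel,
    compute_risk_scores,
    save_signature,
    stratify,
)
from pairsig.survival import (
    cox_fit,
    km_estimate,
    lasso_cox_select,
    logrank_test,
    univariate_screen,
)

logger = logging.getLogger(__name__)

TIME_UNIT_DAYS = {"days": 1.0, "months": 30.44, "years": 365.25}


@dataclass
class PipelineConfig:
    seed: int = 0
    expression: str | None = None
    clinical: str | None = None
    mutations: str | None = None
    validation_expression: list[str] = field(default_factory=list)
    validation_clinical: list[str] = field(default_factory=list)
    signature: str | None = None
    out_dir: str = "pairsig_out"
    mad_threshold: float = 0.5
    mad_scaled: bool = False
    prevalence_low: float = 0.2
    prevalence_high: float = 0.8
    screen_alpha: float = 0.05
    lasso_repetitions: int = 1000
    lasso_folds: int = 10
    lasso_stability_threshold: float = 0.5
    roc_horizons: list[float] = field(default_factory=lambda: list(DEFAULT_HORIZONS))
    cutoff_horizon: float = 1095.0
    cutoff_policy: str = "train_transfer"  # or "per_cohort"
    time_unit: str = "days"
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.prevalence_low < self.prevalence_high <= 1):
            raise ConfigError("prevalence bounds out of range")
        if not (0 <= self.screen_alpha <= 1):
            raise ConfigError("screen_alpha must lie in [0, 1]")
        if self.cutoff_policy not in ("train_transfer", "per_cohort"):
            raise ConfigError(f"unknown cutoff policy: {self.cutoff_policy}")
        if self.time_unit not in TIME_UNIT_DAYS:
            raise ConfigError(f"unknown time unit: {self.time_unit}")
        if any(h <= 0 for h in self.roc_horizons) or self.cutoff_horizon <= 0:
            raise ConfigError("ROC horizons must be positive")
        if len(self.validation_clinical) != len(self.validation_expression):
            raise ConfigError("validation expression/clinical lists must pair up")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def provenance(config: PipelineConfig) -> dict:
    return {
        "pairsig_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
    }


def _load_clinical_days(path: str, time_unit: str) -> pd.DataFrame:
    clinical = io.read_clinical(path)
    factor = TIME_UNIT_DAYS[time_unit]
    if factor != 1.0:
        clinical = clinical.assign(os_days=clinical["os_days"].astype(float) * factor)
    return clinical


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> dict:
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimulationConfig(**sim_kwargs)
    cohort = generate_cohort(sim)
    paths = export_cohort(cohort, out_dir)
    logger.info(
        "simulated cohort: %d samples × %d genes",
        len(cohort.sample_ids),
        cohort.expression.shape[0],
    )
    return {str(k): str(v) for k, v in paths.items()}


def run_build(config: PipelineConfig) -> tuple[SignatureModel, dict]:
    """Build a signature from the training cohort; returns (model, report)."""
    if not config.expression or not config.clinical:
        raise InputError("build requires expression and clinical paths")
    expr = io.read_expression(config.expression)
    clinical = _load_clinical_days(config.clinical, config.time_unit)
    missing = [s for s in expr.columns if s not in clinical.index]
    if missing:
        raise InputError(f"samples lack clinical rows: {missing[:10]}")
    clinical = clinical.loc[expr.columns]

    counts: dict[str, int] = {"genes_total": int(expr.shape[0])}

    genes = mad_filter(expr, config.mad_threshold, scaled=config.mad_scaled)
    counts["genes_mad"] = len(genes)
    logger.info("MAD > %g: %d/%d genes", config.mad_threshold, len(genes), expr.shape[0])
    if len(genes) < 2:
        raise StageAbortError("mad_filter left fewer than 2 genes")

    if config.validation_expression:
        cohorts = [io.read_expression(p) for p in config.validation_expression]
        genes = intersect_available_genes(genes, cohorts)
        counts["genes_available"] = len(genes)
        if len(genes) < 2:
            raise StageAbortError("cross-cohort availability left fewer than 2 genes")

    pm = build_pair_matrix(expr, genes)
    counts["pairs_all"] = pm.n_pairs
    pm = prevalence_filter(pm, config.prevalence_low, config.prevalence_high)
    counts["pairs_prevalence"] = pm.n_pairs
    logger.info("prevalence filter kept %d/%d pairs", pm.n_pairs, counts["pairs_all"])
    if pm.n_pairs == 0:
        raise StageAbortError("prevalence_filter left no pairs")

    screened = univariate_screen(pm, clinical, alpha=config.screen_alpha)
    counts["pairs_screened"] = len(screened)
    logger.info("univariate screen (p < %g): %d pairs", config.screen_alpha, len(screened))
    if len(screened) < 2:
        raise StageAbortError("univariate_screen left fewer than 2 pairs")
    pm_screened = pm.subset(screened)

    selection = lasso_cox_select(
        pm_screened,
        clinical,
        n_repetitions=config.lasso_repetitions,
        n_folds=config.lasso_folds,
        stability_threshold=config.lasso_stability_threshold,
        seed=config.seed,
    )
    counts["pairs_selected"] = len(selection.selected)
    logger.info(
        "LASSO selection: %d pairs (alpha %.4g, %d repetitions)",
        len(selection.selected),
        selection.chosen_alpha,
        selection.n_repetitions,
    )
    if not selection.selected:
        raise StageAbortError("lasso_cox_select selected no pairs")

    pm_final = pm.subset(selection.selected)
    refit = cox_fit(
        pm_final.indicators.T,
        clinical,
        names=[p.pair_id for p in pm_final.pairs],
    )
    entries = [
        (pair, float(beta))
        for pair, beta in zip(pm_final.pairs, refit.coef)
        if beta != 0.0
    ]
    sig = SignatureModel(entries=entries, label="trained")

    # training cutoff: maximum Youden index on the cutoff-horizon ROC
    scores = compute_risk_scores(expr, sig)
    roc = time_dependent_roc(scores, clinical, config.cutoff_horizon)
    cutoff, j = youden_cutoff(roc)
    sig.cutoff = cutoff

    report = {
        "provenance": provenance(config),
        "funnel": counts,
        "selection_frequency": selection.frequency.to_dict(),
        "chosen_alpha": selection.chosen_alpha,
        "refit": refit.summary().to_dict(orient="index"),
        "cutoff": {"value": cutoff, "youden_j": j, "horizon": config.cutoff_horizon},
    }
    return sig, report


def _km_median(curve) -> float | None:
    below = curve.survival <= 0.5
    if not below.any():
        return None
    return float(curve.times[np.argmax(below)])


def evaluate_cohort(
    name: str,
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    sig: SignatureModel,
    horizons: list[float],
    cutoff_horizon: float,
    cutoff_policy: str = "train_transfer",
    mutations: pd.Series | None = None,
) -> tuple[RiskScoreTable, dict]:
    scores = compute_risk_scores(expr, sig)
    clinical = clinical.loc[scores.sample_ids]

    rocs = {}
    for horizon in horizons:
        try:
            roc = time_dependent_roc(scores, clinical, horizon)
            rocs[horizon] = roc.auc
        except InputError as exc:
            logger.warning("%s: ROC at %g days skipped: %s", name, horizon, exc)

    if cutoff_policy == "per_cohort" or sig.cutoff is None:
        roc = time_dependent_roc(scores, clinical, cutoff_horizon)
        cutoff, j = youden_cutoff(roc)
    else:
        cutoff, j = float(sig.cutoff), None
    stratified = stratify(scores, cutoff)

    groups = stratified.groups
    report: dict = {
        "n": len(scores.sample_ids),
        "auc": {str(h): auc for h, auc in rocs.items()},
        "cutoff": cutoff,
        "youden_j": j,
        "n_high": int((groups == "high").sum()),
        "n_low": int((groups == "low").sum()),
    }

    if report["n_high"] > 0 and report["n_low"] > 0:
        grouped = {
            label: clinical.loc[(groups == label).to_numpy()]
            for label in ("high", "low")
        }
        stat, p = logrank_test(grouped)
        report["logrank"] = {"statistic": stat, "p": p}
        report["km_median_days"] = {
            label: _km_median(km_estimate(tbl)) for label, tbl in grouped.items()
        }
        try:
            covariates = [
                c
                for c in ("age_years", "gender", "histology", "stage")
                if c in clinical.columns and clinical[c].nunique() > 1
            ]
            cc = clinical_cox(stratified, clinical, clinical, covariates=covariates)
            report["cox"] = {
                "univariate": cc.univariate.summary().to_dict(orient="index"),
                "multivariate": cc.multivariate.summary().to_dict(orient="index"),
                "risk_score_independent": cc.independent,
            }
        except InputError as exc:
            logger.warning("%s: clinical Cox skipped: %s", name, exc)
        report["associations"] = [
            {
                "variable": a.variable,
                "test": a.test,
                "statistic": a.statistic,
                "p": a.p,
                "effect": a.effect,
                "note": a.note,
            }
            for a in association_suite(stratified, clinical)
        ]
        if mutations is not None:
            shared = [s for s in stratified.sample_ids if s in mutations.index]
            tmb_scores = tmb(mutations.loc[shared])
            hi = tmb_scores[(groups.loc[shared] == "high").to_numpy()]
            lo = tmb_scores[(groups.loc[shared] == "low").to_numpy()]
            from scipy import stats as sps

            wstat, wp = sps.mannwhitneyu(hi, lo, alternative="two-sided")
            rho = correlation(
                stratified.scores.loc[shared], tmb_scores, method="spearman"
            )
            report["tmb"] = {
                "wilcoxon_high_vs_low": {"statistic": float(wstat), "p": float(wp)},
                "spearman_vs_score": {"rho": rho.effect, "p": rho.p},
                "median_high": float(np.median(hi)) if len(hi) else None,
                "median_low": float(np.median(lo)) if len(lo) else None,
            }
    else:
        logger.warning("%s: one risk group is empty; survival contrasts skipped", name)

    return stratified, report


def run_score_evaluate(
    config: PipelineConfig, sig: SignatureModel
) -> tuple[dict[str, RiskScoreTable], dict]:
    """Score and evaluate every configured cohort under a signature."""
    if not config.expression or not config.clinical:
        raise InputError("evaluate requires expression and clinical paths")
    cohorts = [
        ("training", config.expression, config.clinical, config.mutations)
    ]
    for i, (e, c) in enumerate(
        zip(config.validation_expression, config.validation_clinical), start=1
    ):
        cohorts.append((f"validation_{i}", e, c, None))

    all_scores: dict[str, RiskScoreTable] = {}
    report = {"provenance": provenance(config), "signature": sig.label, "cohorts": {}}
    for name, expr_path, clin_path, mut_path in cohorts:
        expr = io.read_expression(expr_path)
        clinical = _load_clinical_days(clin_path, config.time_unit)
        shared = [s for s in expr.columns if s in clinical.index]
        if not shared:
            raise InputError(f"cohort {name}: no samples shared with clinical table")
        missing_genes = sorted(set(sig.genes) - set(expr.index))
        if missing_genes:
            raise InputError(
                f"cohort {name} lacks signature genes: {missing_genes}"
            )
        mutations = io.read_mutations(mut_path) if mut_path else None
        scores, cohort_report = evaluate_cohort(
            name,
            expr[shared],
            clinical.loc[shared],
            sig,
            horizons=list(config.roc_horizons),
            cutoff_horizon=config.cutoff_horizon,
            cutoff_policy=config.cutoff_policy,
            mutations=mutations,
        )
        all_scores[name] = scores
        report["cohorts"][name] = cohort_report
    return all_scores, report


def write_reports(
    out_dir: str | Path,
    sig: SignatureModel | None = None,
    build_report: dict | None = None,
    scores: dict[str, RiskScoreTable] | None = None,
    eval_report: dict | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sig is not None:
        save_signature(sig, out / "signature.tsv")
    if build_report is not None:
        (out / "build_report.json").write_text(json.dumps(build_report, indent=1))
    if scores:
        for name, table in scores.items():
            io.write_scores(table.to_frame(), out / f"scores_{name}.tsv")
    if eval_report is not None:
        (out / "evaluation.json").write_text(json.dumps(eval_report, indent=1))
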