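"""Prognostic and association evaluation.

Time-dependent ROC curves use the Kaplan–Meier cumulative/dynamic estimator:
at horizon t, cases are subjects with an event by t and controls are subjects
surviving past t; subjects censored before t enter through Kaplan–Meier
survival estimates rather than being dropped.  For a threshold c with
positivity rule ``score > c``,

    TP(c) = (1 - S(t | score > c)) * P(score > c) / (1 - S(t))
    FP(c) =      S(t | score > c)  * P(score > c) / S(t)

where S(t | ·) is the product-limit estimate within the score stratum.  With
no censoring this reduces exactly to the binary ROC for the event-by-horizon
label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pairsig.errors import InputError
from pairsig.signature import RiskScoreTable
from pairsig.survival import CoxFit, as_time_event, cox_fit

__all__ = [
    "RocCurve",
    "AssociationResult",
    "ClinicalCoxResult",
    "time_dependent_roc",
    "youden_cutoff",
    "clinical_cox",
    "association_suite",
    "correlation",
    "tmb",
    "YEAR_DAYS",
    "DEFAULT_HORIZONS",
]

YEAR_DAYS = 365.0
DEFAULT_HORIZONS = (365.0, 730.0, 1095.0)  # 1/2/3 years


@dataclass
class RocCurve:
    horizon: float
    thresholds: np.ndarray  # ascending score values
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class AssociationResult:
    variable: str
    test: str  # chi-square | wilcoxon | spearman | pearson
    statistic: float
    p: float
    effect: float | None = None
    note: str = ""


@dataclass
class ClinicalCoxResult:
    univariate: CoxFit
    multivariate: CoxFit
    independent: bool  # risk score keeps p < 0.05 in the multivariate model


def _km_at(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """Product-limit survival at ``horizon`` (fast numpy path)."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    mask = (t <= horizon) & (e == 1)
    if not mask.any():
        return 1.0
    n = len(t)
    surv = 1.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        if t[i] > horizon:
            break
        deaths = int(e[i:j].sum())
        at_risk = n - i
        if deaths:
            surv *= 1.0 - deaths / at_risk
        i = j
    return surv


def time_dependent_roc(scores: RiskScoreTable | pd.Series, records, horizon: float) -> RocCurve:
    """Cumulative-case / dynamic-control ROC at a fixed survival horizon."""
    s = scores.scores if isinstance(scores, RiskScoreTable) else scores
    time, event = as_time_event(records, [str(i) for i in s.index])
    score = s.to_numpy(dtype=float)
    if horizon <= 0:
        raise InputError("horizon must be positive")
    if not ((time <= horizon) & (event == 1)).any():
        raise InputError("no events observed before the horizon")

    s_all = _km_at(time, event, horizon)
    if s_all >= 1.0 or s_all <= 0.0:
        s_all = min(max(s_all, 1e-12), 1 - 1e-12)

    thresholds = np.unique(score)
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, c in enumerate(thresholds):
        pos = score > c
        p_pos = pos.mean()
        if p_pos == 0:
            tp = fp = 0.0
        else:
            s_pos = _km_at(time[pos], event[pos], horizon)
            tp = (1.0 - s_pos) * p_pos / (1.0 - s_all)
            fp = s_pos * p_pos / s_all
        sens[i] = min(max(tp, 0.0), 1.0)
        spec[i] = min(max(1.0 - fp, 0.0), 1.0)

    # integrate in threshold-sweep order: as the threshold drops, the positive
    # set only grows, so points trace the staircase from (0,0) to (1,1)
    fpr = np.concatenate(([0.0], (1.0 - spec)[::-1], [1.0]))
    tpr = np.concatenate(([0.0], sens[::-1], [1.0]))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        horizon=float(horizon),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
    )


def youden_cutoff(roc: RocCurve) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity − 1.

    Ties are broken toward the smallest threshold (the most inclusive
    high-risk group).
    """
    if len(roc.thresholds) == 0:
        raise InputError("degenerate ROC curve")
    j = roc.sensitivity + roc.specificity - 1.0
    # ties (within float fuzz) break toward the smallest threshold
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return float(roc.thresholds[best]), float(j[best])


def _encode_covariates(
    clinical: pd.DataFrame, covariates: list[str]
) -> pd.DataFrame:
    """Numeric columns pass through; categoricals get reference-level dummies."""
    parts = []
    for cov in covariates:
        if cov not in clinical.columns:
            raise InputError(f"covariate {cov!r} absent from clinical table")
        col = clinical[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(cov))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=clinical.index)


def clinical_cox(
    scores: RiskScoreTable,
    clinical: pd.DataFrame,
    records,
    covariates: list[str] = ("age_years", "gender", "histology", "stage"),
) -> ClinicalCoxResult:
    """Univariate (risk score only) and multivariate (score + clinical) Cox.

    The score is flagged "independent" when its multivariate Wald p < 0.05.
    An empty covariate list degenerates the multivariate model to the
    univariate one.
    """
    sample_ids = scores.sample_ids
    clin = clinical.loc[sample_ids]
    design = _encode_covariates(clin, list(covariates))
    X_multi = pd.concat(
        [scores.scores.rename("risk_score"), design.set_axis(scores.scores.index)],
        axis=1,
    )
    mat = X_multi.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat])) < mat.shape[1] + 1:
        raise InputError("collinear covariate encoding in multivariate Cox design")

    uni = cox_fit(scores.scores.to_frame("risk_score"), records)
    multi = cox_fit(X_multi, records)
    score_p = float(multi.p[multi.names.index("risk_score")])
    return ClinicalCoxResult(
        univariate=uni, multivariate=multi, independent=bool(score_p < 0.05)
    )


#: binary clinicopathologic splits used for Wilcoxon comparisons
BINARY_SPLITS = {
    "stage": ("I-II", {"I", "II"}, "III-IV", {"III", "IV"}),
    "t_stage": ("T1-2", {"T1", "T2"}, "T3-4", {"T3", "T4"}),
    "n_stage": ("N0-1", {"N0", "N1"}, "N2-3", {"N2", "N3"}),
    "m_stage": ("M0", {"M0"}, "M1", {"M1"}),
}

CHI_SQUARE_VARIABLES = ["gender", "stage", "t_stage", "n_stage", "m_stage", "histology"]


def association_suite(
    scores: RiskScoreTable, clinical: pd.DataFrame
) -> list[AssociationResult]:
    """Risk-group vs clinical associations.

    Pearson chi-square (no continuity correction) on risk-group × category
    tables for every categorical variable present, and two-sided Wilcoxon
    rank-sum comparisons of the risk-score distribution across the standard
    binary stage splits.
    """
    if scores.groups is None:
        raise InputError("stratify scores before running associations")
    clin = clinical.loc[scores.sample_ids]
    groups = scores.groups
    results: list[AssociationResult] = []

    for var in CHI_SQUARE_VARIABLES:
        if var not in clin.columns:
            continue
        table = pd.crosstab(groups, clin[var].astype(str))
        if table.shape[0] < 2 or table.shape[1] < 2:
            warnings.warn(f"skipping chi-square for {var}: degenerate table")
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        results.append(
            AssociationResult(var, "chi-square", float(chi2), float(p))
        )

    score_vals = scores.scores
    for var, (lab_lo, lo_set, lab_hi, hi_set) in BINARY_SPLITS.items():
        if var not in clin.columns:
            continue
        vals = clin[var].astype(str)
        x = score_vals[vals.isin(lo_set).to_numpy()]
        y = score_vals[vals.isin(hi_set).to_numpy()]
        if len(x) == 0 or len(y) == 0:
            warnings.warn(f"skipping Wilcoxon for {var}: empty split")
            continue
        stat, p = stats.mannwhitneyu(y, x, alternative="two-sided", method="auto")
        results.append(
            AssociationResult(
                var,
                "wilcoxon",
                float(stat),
                float(p),
                effect=float(np.median(y) - np.median(x)),
                note=f"{lab_hi} vs {lab_lo}",
            )
        )
    return results


def correlation(x, y, method: str = "pearson") -> AssociationResult:
    """Pearson or Spearman correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    if len(x) < 3:
        raise InputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero-variance input: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise InputError(f"unknown correlation method: {method}")
    return AssociationResult("correlation", method, float(r), float(p), effect=float(r))


def tmb(mutation_counts: pd.Series, exome_megabases: float = 38.0) -> pd.Series:
    """Tumor mutational burden: somatic mutations per sequenced megabase."""
    if exome_megabases <= 0:
        raise InputError("exome_megabases must be positive")
    counts = pd.Series(mutation_counts, dtype=float)
    if (counts < 0).any():
        raise InputError("negative mutation counts")
    return (counts / exome_megabases).rename("tmb")
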