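"""Censored-survival machinery.

Kaplan–Meier and log-rank are delegated to ``lifelines``.  The Cox
partial-likelihood fitter is implemented here (Newton iterations with
step-halving, Breslow tie handling, standard errors from the observed
information) so that the same Breslow log partial likelihood is shared by the
unpenalized fits, the univariate screen and the cross-validated deviance used
for LASSO penalty selection.  The L1-penalized path itself is computed by
scikit-survival's coxnet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pairsig.errors import InputError
from pairsig.pairs import GenePair, PairMatrix

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "LassoSelection",
    "KaplanMeierCurve",
    "as_time_event",
    "breslow_loglik",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "univariate_pvalues",
    "univariate_screen",
    "lasso_cox_select",
    "lasso_coefs_at",
]


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # days
    event: int  # 1 = death observed, 0 = censored

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InputError(f"negative survival time for {self.sample_id}")
        if self.event not in (0, 1):
            raise InputError(f"event must be 0/1 for {self.sample_id}")


RecordsLike = "Sequence[SurvivalRecord] | pd.DataFrame | tuple"


def as_time_event(
    records, sample_ids: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Coerce survival input to aligned (time, event) arrays.

    Accepts a list of :class:`SurvivalRecord`, a clinical DataFrame with
    ``os_days``/``event`` columns indexed by sample id, or a plain
    ``(time, event)`` pair.  When ``sample_ids`` is given, record-based inputs
    are reordered to match.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in df.index]
            if missing:
                raise InputError(f"samples missing from clinical table: {missing[:10]}")
            df = df.loc[list(sample_ids)]
        return (
            df["os_days"].to_numpy(dtype=float),
            df["event"].to_numpy(dtype=int),
        )
    if isinstance(records, tuple) and len(records) == 2:
        time = np.asarray(records[0], dtype=float)
        event = np.asarray(records[1], dtype=int)
        return time, event
    recs = list(records)
    if sample_ids is not None:
        by_id = {r.sample_id: r for r in recs}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise InputError(f"samples missing from records: {missing[:10]}")
        recs = [by_id[s] for s in sample_ids]
    time = np.array([r.time for r in recs], dtype=float)
    event = np.array([r.event for r in recs], dtype=int)
    return time, event


def records_from_clinical(clinical: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(str(s), float(row["os_days"]), int(row["event"]))
        for s, row in clinical.iterrows()
    ]


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank (lifelines-backed)
# ---------------------------------------------------------------------------


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit step function with S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out


def km_estimate(records) -> KaplanMeierCurve:
    from lifelines import KaplanMeierFitter

    time, event = as_time_event(records)
    if len(time) == 0:
        raise InputError("need at least one record")
    if event.sum() == 0 and np.all(time == 0):
        warnings.warn("degenerate survival data: S == 1 everywhere", stacklevel=2)
        return KaplanMeierCurve(np.array([0.0]), np.array([1.0]))
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    return KaplanMeierCurve(
        sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)
    )


def logrank_test(groups: Mapping[str, object]) -> tuple[float, float]:
    """Mantel–Haenszel log-rank test across ≥2 labelled groups."""
    from lifelines.statistics import multivariate_logrank_test

    if len(groups) < 2:
        raise InputError("log-rank needs at least two groups")
    times, events, labels = [], [], []
    for label, records in groups.items():
        t, e = as_time_event(records)
        if len(t) == 0:
            raise InputError(f"group {label!r} has zero subjects")
        times.append(t)
        events.append(e)
        labels.extend([label] * len(t))
    result = multivariate_logrank_test(
        np.concatenate(times), np.array(labels), np.concatenate(events)
    )
    return float(result.test_statistic), float(result.p_value)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ---------------------------------------------------------------------------


def _sort_by_time(X, time, event):
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order]


def _tie_group_starts(time: np.ndarray) -> np.ndarray:
    """For ascending times, index of the first member of each tie group."""
    new_group = np.r_[True, time[1:] != time[:-1]]
    group_first = np.flatnonzero(new_group)
    group_id = np.cumsum(new_group) - 1
    return group_first[group_id]


def _suffix_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _ll_grad_info(X, time, event, beta, order=2):
    """Breslow log partial likelihood with gradient and observed information.

    Assumes times sorted ascending.  The linear predictor is centered before
    exponentiation for numerical stability (the partial likelihood is
    invariant to that shift).
    """
    n, p = X.shape
    lp = X @ beta
    lp_c = lp - lp.mean()
    w = np.exp(lp_c)
    starts = _tie_group_starts(time)
    ev = event.astype(bool)

    S0 = _suffix_cumsum(w)
    risk0 = S0[starts]
    ll = float(np.sum(lp_c[ev] - np.log(risk0[ev])))
    if order == 0:
        return ll, None, None

    S1 = _suffix_cumsum(w[:, None] * X)
    mean1 = S1[starts] / risk0[:, None]
    grad = (X[ev] - mean1[ev]).sum(axis=0)
    if order == 1:
        return ll, grad, None

    S2 = _suffix_cumsum(w[:, None, None] * X[:, :, None] * X[:, None, :])
    mean2 = S2[starts] / risk0[:, None, None]
    info = (
        mean2[ev] - mean1[ev, :, None] * mean1[ev, None, :]
    ).sum(axis=0)
    return ll, grad, info


def breslow_loglik(X, time, event, beta) -> float:
    """Breslow log partial likelihood at ``beta`` (any observation order)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    Xs, ts, es = _sort_by_time(X, np.asarray(time, float), np.asarray(event, int))
    ll, _, _ = _ll_grad_info(Xs, ts, es, np.asarray(beta, float), order=0)
    return ll


@dataclass
class CoxFit:
    """Result of an unpenalized Cox proportional-hazards fit."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n_iter: int
    n: int
    n_events: int
    flags: list[str] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": np.exp(self.coef),
                "se": self.se,
                "z": self.z,
                "p": self.p,
            },
            index=self.names,
        )


def _newton_cox(
    Xs, ts, es, max_iter: int = 100, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, float, bool, int, list[str]]:
    """Newton–Raphson with step-halving on presorted data."""
    n, p = Xs.shape
    beta = np.zeros(p)
    flags: list[str] = []
    ll, grad, info = _ll_grad_info(Xs, ts, es, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        step = 1.0
        for _ in range(40):
            new_beta = beta + step * delta
            new_ll, new_grad, new_info = _ll_grad_info(Xs, ts, es, new_beta)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            step *= 0.5
        else:
            flags.append("step_halving_failed")
            break
        improved = new_ll - ll
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(grad)) < tol or improved < 1e-13:
            converged = True
            break
    if np.any(np.abs(beta) > 15):
        flags.append("possible_separation")
        converged = False
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return beta, se, ll, converged, it, flags


def cox_fit(
    X,
    records,
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox model by maximizing the Breslow partial likelihood.

    ``X`` is (samples × covariates); constant columns are rejected.  Standard
    errors come from the inverse observed information; p-values are two-sided
    Wald.
    """
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event = as_time_event(records)
    if X.shape[0] != len(time):
        raise InputError("covariate rows must align with records")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    if np.any(np.ptp(X, axis=0) == 0):
        const = [names[i] for i in np.flatnonzero(np.ptp(X, axis=0) == 0)]
        raise InputError(f"constant covariate column(s): {const}")
    if event.sum() == 0:
        raise InputError("no events observed; Cox model is undefined")

    Xs, ts, es = _sort_by_time(X, time, event)
    ll_null, _, _ = _ll_grad_info(Xs, ts, es, np.zeros(X.shape[1]), order=0)
    beta, se, ll, converged, n_iter, flags = _newton_cox(Xs, ts, es, max_iter, tol)
    return CoxFit(
        names=list(names),
        coef=beta,
        se=se,
        loglik=ll,
        loglik_null=ll_null,
        converged=converged,
        n_iter=n_iter,
        n=len(time),
        n_events=int(event.sum()),
        flags=flags,
    )


def cox_score_test(x, records) -> tuple[float, float]:
    """Score (Rao) test for a single covariate at beta = 0.

    For a binary covariate on tie-free data this is algebraically identical
    to the two-group log-rank test.
    """
    x = np.asarray(x, dtype=float)
    time, event = as_time_event(records)
    Xs, ts, es = _sort_by_time(x[:, None], time, event)
    _, grad, info = _ll_grad_info(Xs, ts, es, np.zeros(1))
    if info[0, 0] <= 0:
        raise InputError("degenerate covariate for score test")
    chi2 = float(grad[0] ** 2 / info[0, 0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------


def univariate_pvalues(pm: PairMatrix, records) -> pd.Series:
    """Wald p-value of a single-covariate Cox fit, per pair.

    Non-converged or degenerate fits score p = 1 so the screen drops them
    instead of aborting.
    """
    if pm.n_pairs == 0:
        raise InputError("empty pair matrix")
    time, event = as_time_event(records, pm.sample_ids)
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    mat = pm.indicators.to_numpy(dtype=float)[:, order]
    pvals = np.ones(pm.n_pairs)
    for i in range(pm.n_pairs):
        col = mat[i]
        if np.ptp(col) == 0:
            continue
        beta, se, _, converged, _, _ = _newton_cox(col[:, None], ts, es)
        if converged and np.isfinite(se[0]) and se[0] > 0:
            z = beta[0] / se[0]
            pvals[i] = 2.0 * stats.norm.sf(abs(z))
    return pd.Series(pvals, index=[p.pair_id for p in pm.pairs], name="p")


def univariate_screen(pm: PairMatrix, records, alpha: float = 0.05) -> list[GenePair]:
    """Pairs whose univariate Cox Wald p-value is < ``alpha`` (order kept)."""
    pvals = univariate_pvalues(pm, records)
    return [pair for pair, p in zip(pm.pairs, pvals) if p < alpha]


# ---------------------------------------------------------------------------
# LASSO-Cox selection
# ---------------------------------------------------------------------------


@dataclass
class LassoSelection:
    """Result of repeated cross-validated L1-penalized Cox selection."""

    alphas: np.ndarray
    active_sets: list[list[str]]  # per alpha, on the full-data path
    chosen_alphas: np.ndarray  # one CV winner per repetition
    chosen_alpha: float  # median of the winners
    frequency: pd.Series  # pair_id → selection frequency across repetitions
    selected: list[GenePair]
    n_repetitions: int


def _stratified_folds(event: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold labels balanced on event status."""
    folds = np.empty(len(event), dtype=int)
    for value in (0, 1):
        idx = np.flatnonzero(event == value)
        labels = np.arange(len(idx)) % n_folds
        folds[idx] = labels[rng.permutation(len(idx))]
    return folds


def lasso_cox_select(
    pm: PairMatrix,
    records,
    n_repetitions: int = 1000,
    n_folds: int = 10,
    stability_threshold: float = 0.5,
    n_alphas: int = 50,
    seed: int = 0,
) -> LassoSelection:
    """Select pairs by repeated cross-validated LASSO-Cox.

    One L1 path is fit on the full data.  Each repetition re-randomizes
    ``n_folds`` event-stratified folds and picks the penalty maximizing the
    cross-validated partial likelihood (Verweij–van Houwelingen).  The final
    active set is the pairs active at the winning penalty in more than
    ``stability_threshold`` of repetitions.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if pm.n_pairs < 2:
        raise InputError("need at least 2 pairs for LASSO selection")
    time, event = as_time_event(records, pm.sample_ids)
    n_events = int(event.sum())
    if n_events < 20:
        raise InputError(f"need at least 20 events, got {n_events}")
    if n_events < n_folds:
        raise InputError("fewer events than folds")

    X = pm.indicators.to_numpy(dtype=float).T  # samples × pairs
    y = Surv.from_arrays(event.astype(bool), time)

    full = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01, tol=1e-7
    )
    full.fit(X, y)
    alphas = np.asarray(full.alphas_, dtype=float)
    coefs_full = np.asarray(full.coef_)  # (n_pairs, n_alphas)
    active_sets = [
        [pm.pairs[i].pair_id for i in np.flatnonzero(np.abs(coefs_full[:, a]) > 1e-12)]
        for a in range(len(alphas))
    ]

    rng = np.random.default_rng(seed)
    counts = np.zeros(pm.n_pairs)
    winners = np.empty(n_repetitions)
    for rep in range(n_repetitions):
        folds = _stratified_folds(event, n_folds, rng)
        cvpl = np.zeros(len(alphas))
        for k in range(n_folds):
            train = folds != k
            model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, tol=1e-7)
            model.fit(X[train], y[train])
            fitted = np.asarray(model.coef_)
            fitted_alphas = np.asarray(model.alphas_, dtype=float)
            for ai, alpha in enumerate(alphas):
                ci = int(np.argmin(np.abs(fitted_alphas - alpha)))
                beta = fitted[:, ci]
                cvpl[ai] += breslow_loglik(X, time, event, beta) - breslow_loglik(
                    X[train], time[train], event[train], beta
                )
        best = int(np.argmax(cvpl))
        winners[rep] = alphas[best]
        counts += np.abs(coefs_full[:, best]) > 1e-12

    frequency = pd.Series(
        counts / n_repetitions, index=[p.pair_id for p in pm.pairs], name="frequency"
    )
    selected = [
        pair for pair, f in zip(pm.pairs, frequency) if f > stability_threshold
    ]
    return LassoSelection(
        alphas=alphas,
        active_sets=active_sets,
        chosen_alphas=winners,
        chosen_alpha=float(np.median(winners)),
        frequency=frequency,
        selected=selected,
        n_repetitions=n_repetitions,
    )


def lasso_coefs_at(pm: PairMatrix, records, alpha: float) -> pd.Series:
    """Coefficients of the L1-penalized Cox fit at a single penalty value."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    time, event = as_time_event(records, pm.sample_ids)
    X = pm.indicators.to_numpy(dtype=float).T
    y = Surv.from_arrays(event.astype(bool), time)
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha], tol=1e-9)
    model.fit(X, y)
    return pd.Series(
        np.asarray(model.coef_)[:, 0],
        index=[p.pair_id for p in pm.pairs],
        name="coef",
    )
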