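"""Synthetic survival-cohort generator.

Produces expression / clinical / mutation tables with the structure the
pair-signature analysis expects, plus a ground-truth record, so the whole
pipeline is testable without any external download.

Generative model
----------------
* Expression: per-gene normal on a log2-like scale (location ~ U[2, 10],
  spread ~ U[0.3, 1.5]) plus a per-sample additive offset (a monotone shift
  that never changes within-sample orderings).
* Planted pairs: for each planted pair the indicator is realized by
  construction — a latent Bernoulli decides the sign of a positive gap added
  to the partner gene — so true indicators are controlled exactly rather than
  emergent.  Genes in planted pairs get a widened spread so they survive the
  default variability screen.
* Survival: inverse-transform sampling from a Weibull proportional-hazards
  model with linear predictor ``sum(beta_i * indicator_i)``; independent
  exponential censoring with its rate tuned by bisection to a target
  censored fraction.
* Clinical covariates: categorical draws from configurable proportion maps
  (defaults mirror a large mixed-histology lung cohort); age is normal
  around 66 years.
* Mutation counts: negative binomial with a mean tied to the latent-risk
  stratum (above/below median linear predictor).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pairsig import io
from pairsig.errors import ConfigError, InputError
from pairsig.pairs import GenePair, build_pair_matrix

__all__ = [
    "PlantedPair",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "apply_monotone_distortion",
    "export_cohort",
    "load_cohort",
    "default_planted_pairs",
    "marker_gene_names",
]


def _normalized(counts: dict[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


# Category frequencies of a large mixed-histology lung cohort (known values
# renormalized after removing "unknown").
DEFAULT_CLINICAL_PROPORTIONS: dict[str, dict[str, float]] = {
    "gender": _normalized({"female": 399, "male": 600}),
    "stage": _normalized({"I": 512, "II": 278, "III": 164, "IV": 33}),
    "t_stage": _normalized({"T1": 282, "T2": 557, "T3": 115, "T4": 42}),
    "n_stage": _normalized({"N0": 641, "N1": 222, "N2": 111, "N3": 7}),
    "m_stage": _normalized({"M0": 742, "M1": 32}),
    "histology": _normalized({"LUAD": 504, "LUSC": 495}),
}


def marker_gene_names(n: int) -> list[str]:
    return [f"MG{i:04d}" for i in range(1, n + 1)]


def background_gene_names(n: int) -> list[str]:
    return [f"BG{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PlantedPair:
    """A gene pair whose indicator drives the planted hazard."""

    gene_a: str
    gene_b: str
    beta: float
    prevalence: float = 0.5  # P(indicator == 1)


def default_planted_pairs(
    n_pairs: int, beta: float | list[float], n_marker_genes: int = 90
) -> list[PlantedPair]:
    """Plant ``n_pairs`` disjoint pairs on consecutive marker genes.

    Pairs are oriented in gene-list order so downstream enumeration assigns
    the same orientation.  ``beta`` may be a scalar or one value per pair.
    """
    if 2 * n_pairs > n_marker_genes:
        raise ConfigError("not enough marker genes for the requested pairs")
    betas = [beta] * n_pairs if np.isscalar(beta) else list(beta)
    if len(betas) != n_pairs:
        raise ConfigError("need one beta per planted pair")
    names = marker_gene_names(n_marker_genes)
    return [
        PlantedPair(names[2 * i], names[2 * i + 1], float(betas[i]))
        for i in range(n_pairs)
    ]


@dataclass
class SimulationConfig:
    n_samples: int = 500
    n_marker_genes: int = 90
    n_background_genes: int = 0
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    baseline_shape: float = 1.2
    baseline_scale: float = 1500.0  # days
    censor_rate: float = 0.3
    expression_location: tuple[float, float] = (2.0, 10.0)
    expression_spread: tuple[float, float] = (0.3, 1.5)
    noise_spread: float = 0.2
    clinical_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_CLINICAL_PROPORTIONS.items()
        }
    )
    mutation_rate_by_group: dict[str, float] = field(
        default_factory=lambda: {"high": 250.0, "low": 120.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise InputError("n_samples must be at least 2")
        if self.n_marker_genes < 1 or self.n_background_genes < 0:
            raise ConfigError("gene counts out of range")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ConfigError("censor_rate must lie in [0, 1]")
        for name in ("baseline_shape", "baseline_scale", "noise_spread"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.expression_spread
        if lo <= 0 or hi < lo:
            raise ConfigError("expression_spread must be a positive (lo, hi) range")
        for var, probs in self.clinical_proportions.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"clinical proportions for {var} sum to {total}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"negative proportion for {var}")
        for group, rate in self.mutation_rate_by_group.items():
            if rate <= 0:
                raise ConfigError(f"mutation rate for {group} must be positive")

        marker = set(marker_gene_names(self.n_marker_genes))
        self.planted_pairs = [
            p if isinstance(p, PlantedPair) else PlantedPair(*p)
            for p in self.planted_pairs
        ]
        used: set[str] = set()
        for pair in self.planted_pairs:
            if pair.gene_a == pair.gene_b:
                raise ConfigError(f"planted pair repeats gene {pair.gene_a}")
            for g in (pair.gene_a, pair.gene_b):
                if g not in marker:
                    raise ConfigError(f"planted pair references unknown gene {g}")
                if g in used:
                    raise ConfigError(
                        f"gene {g} appears in more than one planted pair"
                    )
                used.add(g)
            if not (0 < pair.prevalence < 1):
                raise ConfigError("planted prevalence must lie in (0, 1)")
            if not math.isfinite(pair.beta):
                raise ConfigError("planted beta must be finite")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes × samples
    clinical: pd.DataFrame  # indexed by sample_id
    mutations: pd.Series  # sample_id → count
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    def survival_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        time = self.clinical["os_days"].to_numpy(dtype=float)
        event = self.clinical["event"].to_numpy(dtype=int)
        return time, event


def _censoring_rate(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate hitting the target censored fraction.

    Solves mean(1 - exp(-r * T)) = target by bisection; the left side is
    monotone increasing in r.
    """
    if target <= 0:
        return 0.0

    def frac(r: float) -> float:
        return float(np.mean(-np.expm1(-r * event_times)))

    lo, hi = 1e-12, 1e-6
    while frac(hi) < target and hi < 1e6:
        hi *= 10
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; byte-reproducible for a given config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:05d}" for i in range(1, n + 1)]
    genes = marker_gene_names(config.n_marker_genes) + background_gene_names(
        config.n_background_genes
    )

    loc = rng.uniform(*config.expression_location, size=len(genes))
    lo, hi = config.expression_spread
    spread = rng.uniform(lo, hi, size=len(genes))
    gene_index = {g: i for i, g in enumerate(genes)}
    # widen planted genes so the variability screen cannot drop them
    for pair in config.planted_pairs:
        for g in (pair.gene_a, pair.gene_b):
            spread[gene_index[g]] = max(spread[gene_index[g]], 1.0)

    values = rng.normal(loc[:, None], spread[:, None], size=(len(genes), n))
    values += rng.normal(0.0, config.noise_spread, size=n)[None, :]

    # realize planted indicators by construction: latent Bernoulli picks the
    # sign of a strictly positive gap between the paired genes
    eta = np.zeros(n)
    truth_indicators: dict[str, np.ndarray] = {}
    for pair in config.planted_pairs:
        z = rng.random(n) < pair.prevalence
        gap = np.abs(rng.normal(0.0, 1.0, size=n)) + 0.05
        ia, ib = gene_index[pair.gene_a], gene_index[pair.gene_b]
        values[ia] = values[ib] + np.where(z, gap, -gap)
        eta += pair.beta * z
        truth_indicators[f"{pair.gene_a}|{pair.gene_b}"] = z.astype(int)

    expression = pd.DataFrame(
        values, index=pd.Index(genes, name="gene_id"), columns=samples
    )

    # Weibull PH inverse transform: H(t) = (t/scale)^shape * exp(eta)
    u = rng.uniform(size=n)
    event_time = config.baseline_scale * (
        -np.log(u) * np.exp(-eta)
    ) ** (1.0 / config.baseline_shape)

    if config.censor_rate > 0:
        rate = _censoring_rate(event_time, config.censor_rate)
        censor_time = rng.exponential(1.0 / rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    clinical = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    clinical["os_days"] = np.round(observed, 6)
    clinical["event"] = event
    clinical["age_years"] = np.clip(
        np.round(rng.normal(66.0, 9.0, size=n), 1), 30.0, 95.0
    )
    for var, probs in config.clinical_proportions.items():
        cats = list(probs)
        p = np.array([probs[c] for c in cats], dtype=float)
        clinical[var] = rng.choice(cats, size=n, p=p / p.sum())

    if np.ptp(eta) > 0:
        high_risk = eta > np.median(eta)
    else:
        high_risk = rng.random(n) < 0.5
    means = np.where(
        high_risk,
        config.mutation_rate_by_group["high"],
        config.mutation_rate_by_group["low"],
    )
    dispersion = 5.0
    counts = rng.negative_binomial(dispersion, dispersion / (dispersion + means))
    mutations = pd.Series(counts, index=clinical.index, name="mutation_count")

    truth = {
        "planted_pairs": [
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "beta": p.beta}
            for p in config.planted_pairs
        ],
        "linear_predictor": {s: float(e) for s, e in zip(samples, eta)},
        "indicators": {
            pid: ind.tolist() for pid, ind in truth_indicators.items()
        },
        "seed": config.seed,
    }
    return SyntheticCohort(expression, clinical, mutations, truth)


def apply_monotone_distortion(
    expr: pd.DataFrame, kind: str = "affine_positive", seed: int = 0
) -> pd.DataFrame:
    """Apply an independent strictly increasing transform to every sample.

    Emulates a platform shift between cohorts.  Kinds:

    * ``affine_positive`` — ``x * a + b`` with per-sample ``a > 0``.
    * ``power`` — ``x ** g`` with per-sample ``g > 0``; requires
      nonnegative input.
    * ``rank_quantile`` — maps each sample's values onto Gaussian quantiles
      with a per-sample location and scale.

    Within-sample orderings are preserved exactly (verified internally).
    """
    rng = np.random.default_rng(seed)
    vals = expr.to_numpy(dtype=float)
    n_samples = vals.shape[1]

    if kind == "affine_positive":
        scale = rng.uniform(0.5, 3.0, size=n_samples)
        offset = rng.uniform(-5.0, 5.0, size=n_samples)
        out = vals * scale[None, :] + offset[None, :]
    elif kind == "power":
        if (vals < 0).any():
            raise InputError("power distortion requires nonnegative expression")
        gamma = rng.uniform(0.3, 3.0, size=n_samples)
        out = vals ** gamma[None, :]
    elif kind == "rank_quantile":
        from scipy.stats import norm

        mu = rng.uniform(0.0, 10.0, size=n_samples)
        sd = rng.uniform(0.5, 2.0, size=n_samples)
        out = np.empty_like(vals)
        for j in range(n_samples):
            uniq, inverse = np.unique(vals[:, j], return_inverse=True)
            q = norm.ppf((np.arange(len(uniq)) + 0.5) / len(uniq))
            out[:, j] = mu[j] + sd[j] * q[inverse]
    else:
        raise InputError(f"unknown distortion kind: {kind}")

    # monotonicity must hold by construction; guard against regressions
    for j in range(n_samples):
        order = np.argsort(vals[:, j], kind="stable")
        strictly_less = np.diff(vals[order, j]) > 0
        if not np.all(np.diff(out[order, j])[strictly_less] > 0):
            raise RuntimeError("internal error: distortion broke an ordering")

    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def export_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write expression/clinical/mutations TSVs and the truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "clinical": directory / "clinical.tsv",
        "mutations": directory / "mutations.tsv",
        "truth": directory / "truth.json",
    }
    io.write_expression(cohort.expression, paths["expression"])
    io.write_clinical(cohort.clinical, paths["clinical"])
    io.write_mutations(cohort.mutations, paths["mutations"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))
    return paths


def load_cohort(directory: str | Path) -> SyntheticCohort:
    directory = Path(directory)
    expression = io.read_expression(directory / "expression.tsv")
    clinical = io.read_clinical(directory / "clinical.tsv")
    mutations = io.read_mutations(directory / "mutations.tsv")
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticCohort(expression, clinical, mutations, truth)


def realized_pair_indicators(cohort: SyntheticCohort) -> pd.DataFrame:
    """Recompute planted-pair indicators from the expression matrix."""
    rows = {}
    for entry in cohort.truth.get("planted_pairs", []):
        pair = GenePair(entry["gene_a"], entry["gene_b"])
        sub = build_pair_matrix(
            cohort.expression.loc[[pair.gene_a, pair.gene_b]],
            [pair.gene_a, pair.gene_b],
        )
        rows[pair.pair_id] = sub.indicators.iloc[0]
    return pd.DataFrame(rows).T
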