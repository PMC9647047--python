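"""Gene-pair indicator encoding.

A sample is encoded by within-sample orderings: for an oriented pair
``(gene_a, gene_b)`` the feature is 1 iff ``expr[gene_a] > expr[gene_b]`` in
that sample (ties score 0).  Because only the ordering enters, the encoding is
invariant to strictly monotone per-sample transformations — no cross-platform
normalization is needed.

Pipeline order: :func:`mad_filter` (variability screen) →
:func:`intersect_available_genes` (cross-cohort availability) →
:func:`build_pair_matrix` (cyclic single pairing into a 0-or-1 matrix) →
:func:`prevalence_filter` (drop near-constant pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from pairsig.errors import InputError

#: consistency constant making the MAD a normal-scale estimate; off by default
MAD_CONSISTENCY = 1.4826


class GenePair(NamedTuple):
    """Oriented gene pair; indicator is 1 iff expr(gene_a) > expr(gene_b)."""

    gene_a: str
    gene_b: str

    @property
    def pair_id(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"

    def swapped(self) -> "GenePair":
        return GenePair(self.gene_b, self.gene_a)


@dataclass
class PairMatrix:
    """Binary indicator matrix, pairs × samples.

    ``indicators`` is indexed by ``pair_id`` with one 0/1 column per sample;
    ``pairs`` holds the same pairs in row order.
    """

    pairs: list[GenePair]
    indicators: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.indicators):
            raise InputError("pairs and indicator rows disagree in length")
        vals = self.indicators.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise InputError("pair matrix entries must be exactly 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicators.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def prevalence(self) -> pd.Series:
        """Fraction of samples scoring 1, per pair."""
        return self.indicators.mean(axis=1)

    def subset(self, pairs: Sequence[GenePair]) -> "PairMatrix":
        wanted = [p.pair_id for p in pairs]
        return PairMatrix(list(pairs), self.indicators.loc[wanted])


def _check_expression(expr: pd.DataFrame, min_samples: int = 2) -> None:
    if expr.index.duplicated().any() or expr.columns.duplicated().any():
        raise InputError("expression matrix has duplicate gene or sample ids")
    if expr.shape[1] < min_samples:
        raise InputError(f"need at least {min_samples} samples, got {expr.shape[1]}")
    if not np.isfinite(expr.to_numpy()).all():
        raise InputError("expression matrix contains non-finite values")


def median_absolute_deviation(
    expr: pd.DataFrame, scaled: bool = False
) -> pd.Series:
    """Per-gene median of |x - median(x)| across samples.

    ``scaled=True`` multiplies by the 1.4826 consistency constant.
    """
    vals = expr.to_numpy(dtype=float)
    med = np.median(vals, axis=1, keepdims=True)
    mad = np.median(np.abs(vals - med), axis=1)
    if scaled:
        mad = mad * MAD_CONSISTENCY
    return pd.Series(mad, index=expr.index, name="mad")


def mad_filter(
    expr: pd.DataFrame, threshold: float = 0.5, scaled: bool = False
) -> list[str]:
    """Genes whose expression MAD strictly exceeds ``threshold``.

    Input gene order is preserved.  The raw (unscaled) MAD is the default.
    """
    if threshold < 0:
        raise InputError("MAD threshold must be nonnegative")
    _check_expression(expr)
    mad = median_absolute_deviation(expr, scaled=scaled)
    return [g for g, m in mad.items() if m > threshold]


def intersect_available_genes(
    genes: Sequence[str], cohorts: Sequence[pd.DataFrame]
) -> list[str]:
    """Subset of ``genes`` measured in every cohort, original order kept."""
    if len(cohorts) == 0:
        raise InputError("need at least one cohort")
    available = set(genes)
    for cohort in cohorts:
        available &= set(cohort.index)
    kept = [g for g in genes if g in available]
    if not kept:
        warnings.warn("no genes shared across all cohorts", stacklevel=2)
    return kept


def build_pair_matrix(expr: pd.DataFrame, genes: Sequence[str]) -> PairMatrix:
    """Enumerate all unordered gene pairs once and score each sample 0-or-1.

    Orientation: the earlier gene in ``genes`` becomes ``gene_a``; the
    indicator is 1 iff its value strictly exceeds ``gene_b``'s (ties → 0).
    Produces n·(n−1)/2 pairs.
    """
    genes = list(genes)
    if len(genes) != len(set(genes)):
        raise InputError("gene list contains duplicates")
    if len(genes) < 2:
        raise InputError("pairing requires at least 2 genes")
    unknown = [g for g in genes if g not in expr.index]
    if unknown:
        raise InputError(f"genes absent from expression matrix: {unknown[:10]}")
    _check_expression(expr)

    vals = expr.loc[genes].to_numpy(dtype=float)
    ia, ib = np.triu_indices(len(genes), k=1)
    indicators = (vals[ia] > vals[ib]).astype(np.int8)
    pairs = [GenePair(genes[a], genes[b]) for a, b in zip(ia, ib)]
    frame = pd.DataFrame(
        indicators, index=[p.pair_id for p in pairs], columns=expr.columns
    )
    return PairMatrix(pairs, frame)


def prevalence_filter(
    pm: PairMatrix, low: float = 0.2, high: float = 0.8
) -> PairMatrix:
    """Keep pairs whose fraction of 1s lies in the closed interval [low, high].

    Pairs scoring 1 (equivalently 0) in less than ``low`` or more than
    ``high`` of samples carry little variation and are dropped.  Boundaries
    are inclusive; row order is preserved.
    """
    if not (0 <= low < high <= 1):
        raise InputError("require 0 <= low < high <= 1")
    if pm.n_pairs == 0:
        raise InputError("empty pair matrix")
    frac = pm.prevalence().to_numpy()
    keep = (frac >= low) & (frac <= high)
    kept_pairs = [p for p, k in zip(pm.pairs, keep) if k]
    return PairMatrix(kept_pairs, pm.indicators.loc[keep])
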