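"""Signature data model, risk scoring and risk-group assignment.

A signature is an ordered list of oriented gene pairs with Cox regression
coefficients.  A sample's risk score is the coefficient-weighted sum of its
pair indicators::

    risk_score = sum(beta_i * [expr(gene_a_i) > expr(gene_b_i)])

The published 23-pair model ships as the packaged fixture ``"table2"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from pairsig import io
from pairsig.errors import FormatError, InputError
from pairsig.pairs import GenePair

__all__ = [
    "SignatureModel",
    "RiskScoreTable",
    "load_signature",
    "save_signature",
    "compute_risk_scores",
    "stratify",
]

PACKAGED_FIXTURES = {"table2": "table2_signature.tsv"}


@dataclass
class SignatureModel:
    """Ordered gene pairs with coefficients and an optional risk cutoff."""

    entries: list[tuple[GenePair, float]]
    cutoff: float | None = None
    label: str = "signature"

    def __post_init__(self) -> None:
        seen = set()
        for pair, beta in self.entries:
            if pair in seen:
                raise FormatError(f"duplicate pair in signature: {pair.pair_id}")
            seen.add(pair)
            if not math.isfinite(beta) or beta == 0:
                raise FormatError(
                    f"coefficient for {pair.pair_id} must be finite and nonzero"
                )

    @property
    def pairs(self) -> list[GenePair]:
        return [p for p, _ in self.entries]

    @property
    def betas(self) -> np.ndarray:
        return np.array([b for _, b in self.entries], dtype=float)

    @property
    def genes(self) -> list[str]:
        """Distinct gene symbols across both pair members, first-seen order."""
        out: list[str] = []
        for pair, _ in self.entries:
            for g in (pair.gene_a, pair.gene_b):
                if g not in out:
                    out.append(g)
        return out

    def score_bounds(self) -> tuple[float, float]:
        betas = self.betas
        return float(betas[betas < 0].sum()), float(betas[betas > 0].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": [p.pair_id for p in self.pairs],
                "gene_a": [p.gene_a for p in self.pairs],
                "gene_b": [p.gene_b for p in self.pairs],
                "coefficient": self.betas,
            }
        )


@dataclass
class RiskScoreTable:
    """Per-sample risk scores, with high/low labels once a cutoff is applied."""

    scores: pd.Series
    cutoff: float | None = None
    groups: pd.Series | None = field(default=None)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.scores.index]

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.rename("risk_score").to_frame()
        if self.groups is not None:
            out["risk_group"] = self.groups
        return out


def load_signature(source: str | Path) -> SignatureModel:
    """Load a signature from a TSV file or a packaged fixture id.

    ``load_signature("table2")`` returns the packaged 23-pair model.
    """
    if isinstance(source, str) and source in PACKAGED_FIXTURES:
        ref = resources.files("pairsig") / "data" / PACKAGED_FIXTURES[source]
        with resources.as_file(ref) as path:
            df = io.read_signature_table(path)
        label = source
    else:
        df = io.read_signature_table(source)
        label = str(source)
    entries = [
        (GenePair(str(r.gene_a), str(r.gene_b)), float(r.coefficient))
        for r in df.itertuples()
    ]
    return SignatureModel(entries=entries, label=label)


def save_signature(sig: SignatureModel, path: str | Path) -> None:
    io.write_signature_table(sig.to_frame(), path)


def compute_risk_scores(expr: pd.DataFrame, sig: SignatureModel) -> RiskScoreTable:
    """Score every sample of an expression matrix under a signature.

    Each pair contributes ``beta`` iff ``expr(gene_a) > expr(gene_b)`` in the
    sample.  Samples are scored independently; the result is invariant to any
    strictly increasing per-sample transform of the expression values.
    """
    missing = sorted(set(sig.genes) - set(expr.index.astype(str)))
    if missing:
        raise InputError(f"signature genes absent from expression matrix: {missing}")
    a_vals = expr.loc[[p.gene_a for p in sig.pairs]].to_numpy(dtype=float)
    b_vals = expr.loc[[p.gene_b for p in sig.pairs]].to_numpy(dtype=float)
    indicators = (a_vals > b_vals).astype(float)
    scores = indicators.T @ sig.betas
    return RiskScoreTable(
        scores=pd.Series(scores, index=expr.columns, name="risk_score")
    )


def stratify(table: RiskScoreTable, cutoff: float) -> RiskScoreTable:
    """Assign high/low groups: score > cutoff → high, score ≤ cutoff → low."""
    if not math.isfinite(cutoff):
        raise InputError("cutoff must be finite")
    groups = pd.Series(
        np.where(table.scores.to_numpy() > cutoff, "high", "low"),
        index=table.scores.index,
        name="risk_group",
    )
    return RiskScoreTable(scores=table.scores, cutoff=cutoff, groups=groups)
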