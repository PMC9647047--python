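"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated text.  Floating point values are written with 12
significant digits so that export → import round-trips are lossless at that
precision.

* ``expression.tsv`` — first column ``gene_id``, one column per sample.
* ``clinical.tsv`` — ``sample_id, os_days, event, age_years, gender, stage,
  t_stage, n_stage, m_stage, histology``.
* ``mutations.tsv`` — ``sample_id, mutation_count``.
* ``signature.tsv`` — ``pair_id, gene_a, gene_b, coefficient``.
* ``scores.tsv`` — ``sample_id, risk_score[, risk_group]``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from pairsig.errors import FormatError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"

CLINICAL_COLUMNS = [
    "os_days",
    "event",
    "age_years",
    "gender",
    "stage",
    "t_stage",
    "n_stage",
    "m_stage",
    "histology",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Load a genes × samples expression matrix.

    Genes containing any missing value are dropped with a warning; duplicate
    gene or sample identifiers are a format error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in {path}: {dup[:5]}")
    if df.columns.duplicated().any():
        raise FormatError(f"duplicate sample ids in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression values in {path}: {exc}") from exc
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning(
            "dropping %d gene(s) with missing values from %s", n_missing, path
        )
        df = df.dropna(axis=0)
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr = expr.copy()
    expr.index.name = "gene_id"
    expr.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"clinical table {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    missing = [c for c in ("os_days", "event") if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table {path} lacks columns {missing}")
    if df.index.duplicated().any():
        raise FormatError(f"duplicate sample ids in {path}")
    if (df["os_days"].astype(float) < 0).any():
        raise FormatError(f"negative survival times in {path}")
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"event column of {path} must be 0/1")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_mutations(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "mutation_count"):
        if col not in df.columns:
            raise FormatError(f"mutation table {path} lacks column {col}")
    counts = df.set_index("sample_id")["mutation_count"].astype(int)
    if (counts < 0).any():
        raise FormatError(f"negative mutation counts in {path}")
    return counts


def write_mutations(counts: pd.Series, path: str | Path) -> None:
    out = counts.rename("mutation_count").to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_signature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["pair_id", "gene_a", "gene_b", "coefficient"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"signature file {path} lacks columns {missing}")
    try:
        df["coefficient"] = df["coefficient"].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric coefficient in {path}: {exc}") from exc
    if df["coefficient"].isna().any():
        raise FormatError(f"missing coefficient in {path}")
    return df


def write_signature_table(df: pd.DataFrame, path: str | Path) -> None:
    # repr-based formatting keeps the coefficient column bit-exact on round trip
    out = df.copy()
    out["coefficient"] = [np.format_float_positional(v, trim="-") for v in out["coefficient"]]
    out.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "risk_score" not in df.columns:
        raise FormatError(f"scores file {path} lacks sample_id/risk_score columns")
    return df.set_index("sample_id")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_pair_matrix_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise FormatError(f"pair matrix {path} contains values other than 0/1")
    return df.astype(np.int8)


def write_pair_matrix_table(indicators: pd.DataFrame, path: str | Path) -> None:
    out = indicators.copy()
    out.index.name = "pair_id"
    out.to_csv(path, sep="\t")
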