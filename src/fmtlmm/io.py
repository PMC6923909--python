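"""Reading and writing expression matrices, sample sheets and results tables.

Expression matrices are TSV/CSV with the gene identifier in the first column and
one column per sample of log2 expression.  Sample sheets carry sample_id, group
and subject columns; row order need not match the matrix — the two are joined by
sample_id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExperimentDesign

__all__ = ["read_expression", "read_samples", "align", "write_results"]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path) -> pd.DataFrame:
    """Load a genes × samples matrix; index = gene ids, columns = sample ids."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expression matrix has no sample columns")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.isna().sum().sum()
        raise ValueError(f"{path}: {bad} missing/non-numeric expression values")
    values.index.name = "gene_id"
    return values


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    required = {"sample_id", "group", "subject"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_ids in sample sheet")
    return df


def align(matrix: pd.DataFrame, samples: pd.DataFrame):
    """Join matrix columns to the sample sheet; returns (Y, gene_ids, design)."""
    sheet_ids = list(samples["sample_id"].astype(str))
    cols = [str(c) for c in matrix.columns]
    missing = set(sheet_ids) - set(cols)
    if missing:
        raise ValueError(f"samples missing from matrix: {sorted(missing)[:5]} ...")
    extra = set(cols) - set(sheet_ids)
    ordered = matrix[[c for c in matrix.columns if str(c) in set(sheet_ids)]]
    ordered = ordered.loc[:, [cols[cols.index(s)] for s in sheet_ids]]
    design = ExperimentDesign.from_frame(samples)
    if extra:
        import logging

        logging.getLogger(__name__).warning(
            "%d matrix columns not in sample sheet are ignored", len(extra))
    return ordered.to_numpy(dtype=float), np.asarray(matrix.index), design


def write_results(results: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, sep=_sep(path), index=False)
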