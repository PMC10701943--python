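"""Readers and writers for matrices, batch labels and covariates.

Matrix files are genes x samples TSV/CSV: first column gene ids,
header row sample ids; the delimiter is sniffed from the extension
(.csv -> comma, anything else -> tab). Batch files are two-column TSV
(sample id, batch label) with a header. Covariate files are TSV keyed
by sample id. Expression values are written with 17 significant
digits and counts as plain integers so write -> read round-trips are
exact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .data_model import BatchDesign, CountMatrix, ExpressionMatrix
from .errors import ParseError, ShapeMismatchError

__all__ = [
    "read_expression",
    "read_counts",
    "read_batch",
    "read_covariates",
    "write_matrix",
]


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        # round_trip parsing: 17-significant-digit output must read
        # back bit-identical
        df = pd.read_csv(
            path, sep=_sep(path), index_col=0, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    return df


def read_expression(path) -> ExpressionMatrix:
    """Read a real-valued genes x samples matrix."""
    df = _read_table(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value: {exc}") from exc
    return ExpressionMatrix(df)


def read_counts(path) -> CountMatrix:
    """Read an integer genes x samples matrix; rejects decimals with
    the offending coordinates."""
    df = _read_table(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric count value: {exc}") from exc
    return CountMatrix(df)


def read_batch(path) -> tuple[list, list]:
    """Read the two-column (sample id, batch) table; returns
    (sample_ids, labels) in file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (sample, batch)")
    samples = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, 1].astype(str).tolist()
    return samples, labels


def read_covariates(path) -> pd.DataFrame:
    """Read the samples x p numeric covariate table keyed by sample id."""
    df = _read_table(path)
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ParseError(
            f"{path}: covariates must be numerically encoded: {exc}"
        ) from exc


def build_design_from_files(
    matrix,
    batch_path,
    covariates_path=None,
    ref_batch: Optional[str] = None,
) -> BatchDesign:
    """Assemble a BatchDesign for a loaded matrix, reconciling ids."""
    samples, labels = read_batch(batch_path)
    if len(set(samples)) != len(samples):
        raise ParseError(f"{batch_path}: duplicated sample ids")
    missing = [s for s in matrix.sample_ids if s not in set(samples)]
    if missing:
        raise ShapeMismatchError(
            f"batch file lacks samples present in the matrix: {missing[:5]}"
        )
    extra = [s for s in samples if s not in set(matrix.sample_ids)]
    if extra:
        raise ShapeMismatchError(
            f"batch file lists unknown samples: {extra[:5]}"
        )
    cov = read_covariates(covariates_path) if covariates_path else None
    if cov is not None:
        lacking = [s for s in matrix.sample_ids if s not in cov.index]
        if lacking:
            raise ShapeMismatchError(
                f"covariate table lacks samples: {lacking[:5]}"
            )
        cov = cov.loc[matrix.sample_ids]
    return BatchDesign(
        batch_of=dict(zip(samples, labels)),
        covariates=cov,
        ref_batch=ref_batch,
    )


def write_matrix(matrix, path) -> None:
    """Write a matrix back to TSV/CSV (delimiter from the extension)."""
    if isinstance(matrix, (ExpressionMatrix, CountMatrix)):
        df = matrix.data
    else:
        df = matrix
    import numpy as np

    if np.issubdtype(df.to_numpy().dtype, np.integer):
        df.to_csv(path, sep=_sep(path))
    else:
        df.to_csv(path, sep=_sep(path), float_format="%.17g")
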