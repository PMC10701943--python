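"""Domain containers and design-matrix construction.

Both correctors model expression of gene ``g`` in sample ``j`` of batch
``i`` as a gene baseline plus covariate effects plus an additive batch
term (``alpha_g + X_j beta_g + gamma_gi``, on the log scale for counts).
The shared plumbing here encodes the batch membership as indicator
columns (one per batch, no global intercept) followed by the numeric
covariate columns, and checks that this combined design is full rank so
that batch effects are identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfoundedDesignError,
    ShapeMismatchError,
    SingleBatchError,
    SingleSampleBatchError,
)

__all__ = [
    "ExpressionMatrix",
    "CountMatrix",
    "BatchDesign",
    "DesignMatrix",
    "validate_and_build_design",
]

#: relative singular-value cutoff for the numerical rank check
_RANK_TOL = 1e-8


@dataclass
class ExpressionMatrix:
    """Genes x samples table of real-valued (log-scale) expression.

    Missing values (NaN) are permitted and flagged; infinite values are
    rejected. Gene and sample identifiers must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).astype(float)
        if df.index.duplicated().any():
            raise ShapeMismatchError("duplicated gene ids")
        if df.columns.duplicated().any():
            raise ShapeMismatchError("duplicated sample ids")
        if df.shape[1] < 2:
            raise ShapeMismatchError("need at least 2 samples")
        if np.isinf(df.to_numpy()).any():
            raise ValueError("infinite expression values are not allowed")
        self.data = df

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.data.to_numpy()).any())


@dataclass
class CountMatrix:
    """Genes x samples table of non-negative integer counts.

    No missing values; entries must be integral and >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        if df.index.duplicated().any():
            raise ShapeMismatchError("duplicated gene ids")
        if df.columns.duplicated().any():
            raise ShapeMismatchError("duplicated sample ids")
        if df.shape[1] < 2:
            raise ShapeMismatchError("need at least 2 samples")
        arr = df.to_numpy()
        if np.issubdtype(arr.dtype, np.floating):
            if np.isnan(arr).any():
                raise ValueError("count matrix contains missing values")
            if not np.all(arr == np.floor(arr)):
                bad = np.argwhere(arr != np.floor(arr))[0]
                raise ValueError(
                    f"non-integer count at gene {df.index[bad[0]]!r}, "
                    f"sample {df.columns[bad[1]]!r}"
                )
            df = df.astype(np.int64)
            arr = df.to_numpy()
        elif not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("count matrix must be numeric")
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        self.data = df

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class BatchDesign:
    """Per-sample batch labels plus optional numeric covariates.

    Batch labels are opaque strings; the batch order is their
    first-appearance order in the label sequence, which fixes the column
    order of every per-batch parameter table downstream. Covariates are
    supplied already numerically encoded (no intercept column);
    categorical expansion is the caller's job.
    """

    batch_of: Mapping[str, str]
    covariates: Optional[pd.DataFrame] = None
    ref_batch: Optional[str] = None
    batches: list = field(init=False)

    def __post_init__(self) -> None:
        self.batch_of = dict(self.batch_of)
        seen: dict = {}
        for b in self.batch_of.values():
            seen.setdefault(b, None)
        self.batches = list(seen)
        if len(self.batches) < 2:
            raise SingleBatchError(
                f"need at least 2 batches, got {len(self.batches)}"
            )
        if self.ref_batch is not None and self.ref_batch not in self.batches:
            raise ValueError(
                f"ref_batch {self.ref_batch!r} is not a batch label"
            )
        if self.covariates is not None:
            cov = pd.DataFrame(self.covariates).astype(float)
            missing = [s for s in self.batch_of if s not in cov.index]
            if missing:
                raise ShapeMismatchError(
                    f"covariates missing for samples: {missing[:5]}"
                )
            self.covariates = cov

    @classmethod
    def from_labels(
        cls,
        sample_ids: Sequence,
        batch_labels: Sequence,
        covariates: Optional[pd.DataFrame] = None,
        ref_batch: Optional[str] = None,
    ) -> "BatchDesign":
        if len(sample_ids) != len(batch_labels):
            raise ShapeMismatchError(
                f"{len(sample_ids)} samples but {len(batch_labels)} labels"
            )
        return cls(
            batch_of={s: str(b) for s, b in zip(sample_ids, batch_labels)},
            covariates=covariates,
            ref_batch=None if ref_batch is None else str(ref_batch),
        )

    @property
    def sizes(self) -> dict:
        out = {b: 0 for b in self.batches}
        for b in self.batch_of.values():
            out[b] += 1
        return out


@dataclass
class DesignMatrix:
    """Full design: one indicator column per batch, then covariates.

    The batch-indicator columns partition the samples (they sum to the
    all-ones vector), and the whole matrix is full column rank.
    """

    matrix: np.ndarray  # samples x (n_batches + n_covariates)
    sample_ids: list
    batches: list
    covariate_names: list
    batch_index: np.ndarray  # per-sample integer batch index
    ref_index: Optional[int] = None

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def batch_part(self) -> np.ndarray:
        return self.matrix[:, : self.n_batches]

    @property
    def covariate_part(self) -> np.ndarray:
        return self.matrix[:, self.n_batches :]

    @property
    def batch_sizes(self) -> np.ndarray:
        return np.bincount(self.batch_index, minlength=self.n_batches)

    def samples_of(self, i: int) -> np.ndarray:
        """Column indices of samples belonging to batch ``i``."""
        return np.flatnonzero(self.batch_index == i)


def validate_and_build_design(
    matrix,
    batches: BatchDesign,
    mode: str = "normal",
    mean_only: bool = False,
) -> DesignMatrix:
    """Check inputs against each other and build the full design.

    Samples are put in the matrix's column order. ``mode='count'``
    additionally requires every batch to hold at least 2 samples (the
    per-batch dispersion is unidentifiable otherwise); in normal mode a
    singleton batch is legal only with ``mean_only`` set, because its
    variance never enters a location-only adjustment.
    """
    if mode not in ("normal", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    sample_ids = list(matrix.sample_ids)
    design_samples = set(batches.batch_of)
    mat_samples = set(sample_ids)
    if design_samples != mat_samples:
        only_mat = sorted(mat_samples - design_samples)
        only_des = sorted(design_samples - mat_samples)
        raise ShapeMismatchError(
            f"sample ids disagree; only in matrix: {only_mat[:5]}, "
            f"only in batch table: {only_des[:5]}"
        )

    labels = [batches.batch_of[s] for s in sample_ids]
    batch_order = batches.batches
    pos = {b: i for i, b in enumerate(batch_order)}
    batch_index = np.array([pos[b] for b in labels], dtype=np.intp)
    n = len(sample_ids)
    k = len(batch_order)
    indicators = np.zeros((n, k))
    indicators[np.arange(n), batch_index] = 1.0

    sizes = np.bincount(batch_index, minlength=k)
    if mode == "count":
        small = [batch_order[i] for i in np.flatnonzero(sizes < 2)]
        if small:
            raise SingleSampleBatchError(
                f"count model requires >= 2 samples per batch; "
                f"too small: {small}"
            )
    else:
        small = [batch_order[i] for i in np.flatnonzero(sizes < 2)]
        if small and not mean_only:
            raise SingleSampleBatchError(
                f"batches with a single sample ({small}) are only "
                f"supported with mean_only correction"
            )

    cov_names: list = []
    if batches.covariates is not None and batches.covariates.shape[1] > 0:
        cov = batches.covariates.loc[sample_ids]
        cov_names = list(cov.columns)
        full = np.hstack([indicators, cov.to_numpy()])
    else:
        full = indicators

    svals = np.linalg.svd(full, compute_uv=False)
    rank = int(np.sum(svals > _RANK_TOL * svals[0]))
    if rank < full.shape[1]:
        raise ConfoundedDesignError(
            "design is rank deficient: a covariate is collinear with the "
            "batch indicators (or with another covariate)"
        )

    ref_index = None
    if batches.ref_batch is not None:
        ref_index = pos[batches.ref_batch]

    return DesignMatrix(
        matrix=full,
        sample_ids=sample_ids,
        batches=list(batch_order),
        covariate_names=cov_names,
        batch_index=batch_index,
        ref_index=ref_index,
    )


def as_expression(matrix) -> ExpressionMatrix:
    """Coerce a DataFrame (or ExpressionMatrix) to ExpressionMatrix."""
    if isinstance(matrix, ExpressionMatrix):
        return matrix
    return ExpressionMatrix(pd.DataFrame(matrix))


def as_counts(matrix) -> CountMatrix:
    """Coerce a DataFrame (or CountMatrix) to CountMatrix."""
    if isinstance(matrix, CountMatrix):
        return matrix
    return CountMatrix(pd.DataFrame(matrix))
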