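"""Validation metrics: agreement between corrected matrices and
residual-batch-effect statistics."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data_model import BatchDesign, as_expression, validate_and_build_design
from .errors import DegenerateGeneWarning, ShapeMismatchError

__all__ = ["DiffSummary", "relative_difference_summary", "batch_f_statistics"]


@dataclass
class DiffSummary:
    """Summary of entry-wise relative differences (a - b) / b.

    The 95% interval is the empirical 2.5/97.5 percentile of the
    per-entry relative differences; ``relative_squared_error`` is
    sum((a-b)^2) / sum(b^2). Entries with b = 0 are excluded from the
    ratios and counted in ``n_excluded``.
    """

    mean_rel_diff: float
    ci95_low: float
    ci95_high: float
    relative_squared_error: float
    n_entries: int
    n_excluded: int

    def to_dict(self) -> dict:
        return asdict(self)


def relative_difference_summary(a, b) -> DiffSummary:
    """Compare two corrected matrices entry by entry."""
    am = as_expression(a)
    bm = as_expression(b)
    if am.gene_ids != bm.gene_ids or am.sample_ids != bm.sample_ids:
        raise ShapeMismatchError("matrices have different gene/sample ids")
    A = am.values
    B = bm.values
    ok = B != 0
    rel = (A[ok] - B[ok]) / B[ok]
    rse = float(np.sum((A - B) ** 2) / np.sum(B**2))
    return DiffSummary(
        mean_rel_diff=float(rel.mean()),
        ci95_low=float(np.percentile(rel, 2.5)),
        ci95_high=float(np.percentile(rel, 97.5)),
        relative_squared_error=rse,
        n_entries=int(rel.size),
        n_excluded=int((~ok).sum()),
    )


def batch_f_statistics(matrix, batch) -> pd.Series:
    """One-way ANOVA F per gene with batch as the factor.

    F = (between-batch SS / (k - 1)) / (within-batch SS / (N - k)).
    Genes with zero within-batch variance get F = +inf with a warning.
    Values near 1 indicate no residual batch effect on the mean.
    """
    expr = as_expression(matrix)
    bd = (
        batch
        if isinstance(batch, BatchDesign)
        else BatchDesign.from_labels(expr.sample_ids, batch)
    )
    design = validate_and_build_design(expr, bd, "normal")
    Y = expr.values
    G, N = Y.shape
    k = design.n_batches
    grand = Y.mean(axis=1)
    ss_between = np.zeros(G)
    ss_within = np.zeros(G)
    for i in range(k):
        cols = design.samples_of(i)
        bm = Y[:, cols].mean(axis=1)
        ss_between += cols.size * (bm - grand) ** 2
        ss_within += np.sum((Y[:, cols] - bm[:, None]) ** 2, axis=1)
    zero_within = ss_within == 0
    if zero_within.any():
        warnings.warn(
            f"{int(zero_within.sum())} gene(s) have zero within-batch "
            f"variance; F reported as +inf",
            DegenerateGeneWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (N - k))
    return pd.Series(f, index=expr.gene_ids, name="F")
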