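"""Batch correction of RNA-Seq raw counts by NB quantile matching.

Each observed count is located on the CDF of its fitted
batch-containing negative binomial distribution and mapped to the same
quantile of a batch-free distribution whose mean uses a pooled
(batch-size-weighted, or reference-batch) baseline in place of the
batch coefficient, and whose dispersion is pooled the same way. The
map outputs integers, so raw counts go in and adjusted counts come
out with no preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

from .data_model import (
    BatchDesign,
    CountMatrix,
    DesignMatrix,
    as_counts,
    validate_and_build_design,
)
from .nbglm import DispersionEstimates, NBFit, estimate_dispersions, fit_nb_glm

__all__ = [
    "CountAdjustmentPlan",
    "build_adjustment_plan",
    "match_quantiles",
    "pycombat_seq",
]

#: quantiles this close to 1 are left untouched (deep-tail guard)
_TAIL_TOL = 1e-4
#: dispersions below this are numerically Poisson (1/phi overflows or
#: the NB is indistinguishable from its Poisson limit)
_PHI_EPS = 1e-8


@dataclass
class CountAdjustmentPlan:
    """Entry-wise NB parameters before and after batch removal."""

    mu_batch: np.ndarray   # (G, N) means under the full model
    phi_batch: np.ndarray  # (G, N) sample's batch dispersion
    mu_free: np.ndarray    # (G, N) batch-free means
    phi_free: np.ndarray   # (G,) pooled dispersion


def build_adjustment_plan(
    fit: NBFit,
    dispersions: DispersionEstimates,
    design: DesignMatrix,
) -> CountAdjustmentPlan:
    """Derive the batch-free target distribution from the fit.

    The batch-free baseline is the batch-size-weighted average of the
    per-batch coefficients (or the reference batch's coefficient), and
    the pooled dispersion is weighted the same way; covariate effects
    and library-size offsets are kept, so only the batch term changes.
    """
    k = design.n_batches
    sizes = design.batch_sizes.astype(float)
    w = sizes / sizes.sum()
    batch_coef = fit.coefficients[:, :k]
    beta = fit.coefficients[:, k:]
    if design.ref_index is None:
        alpha = batch_coef @ w
        phi_free = dispersions.genewise @ w
    else:
        alpha = batch_coef[:, design.ref_index]
        phi_free = dispersions.genewise[:, design.ref_index]

    cov_term = (
        beta @ design.covariate_part.T if beta.shape[1] else 0.0
    )
    mu_free = np.exp(
        np.clip(alpha[:, None] + cov_term, -30, 30) + fit.offsets[None, :]
    )
    phi_batch = dispersions.genewise[:, design.batch_index]
    return CountAdjustmentPlan(
        mu_batch=fit.fitted_mu,
        phi_batch=phi_batch,
        mu_free=mu_free,
        phi_free=phi_free,
    )


def _cdf(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    out = np.empty(y.shape)
    pois = phi <= _PHI_EPS
    if pois.any():
        out[pois] = poisson.cdf(y[pois], mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        out[nb] = nbinom.cdf(y[nb], r, r / (r + mu[nb]))
    return out


def _quantile(p: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Smallest integer k with CDF(k) >= p."""
    out = np.empty(p.shape)
    pois = phi <= _PHI_EPS
    if pois.any():
        out[pois] = poisson.ppf(p[pois], mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        out[nb] = nbinom.ppf(p[nb], r, r / (r + mu[nb]))
    return out


def match_quantiles(counts, plan: CountAdjustmentPlan):
    """Map every count through its batch CDF to the batch-free quantile.

    Entry rules: counts of 0 or 1 pass through; the quantile is taken
    at count - 1 under the batch distribution; quantiles within 1e-4 of
    1 pass through (the discrete quantile is unstable that deep in the
    tail); otherwise the output is 1 + the batch-free quantile, which
    makes the map the identity when the two distributions coincide.
    Zero-dispersion entries use the Poisson CDF/quantile.
    """
    cm = as_counts(counts)
    Y = cm.values
    G, N = Y.shape
    out = Y.astype(np.int64).copy()
    phi_free = np.broadcast_to(plan.phi_free[:, None], (G, N))

    work = Y > 1
    if work.any():
        y = Y[work].astype(float)
        p = _cdf(y - 1.0, plan.mu_batch[work], plan.phi_batch[work])
        keep = np.abs(p - 1.0) < _TAIL_TOL
        adj = np.empty(y.shape)
        adj[keep] = y[keep]
        if (~keep).any():
            q = _quantile(
                p[~keep], plan.mu_free[work][~keep], phi_free[work][~keep]
            )
            adj[~keep] = 1.0 + q
        out[work] = adj.astype(np.int64)

    res = pd.DataFrame(out, index=cm.gene_ids, columns=cm.sample_ids)
    if isinstance(counts, CountMatrix):
        return CountMatrix(res)
    if isinstance(counts, pd.DataFrame):
        return res
    return CountMatrix(res)


def pycombat_seq(
    counts,
    batch,
    covariates: Optional[pd.DataFrame] = None,
    ref_batch: Optional[str] = None,
):
    """Correct batch effects in a raw RNA-Seq count matrix.

    Parameters
    ----------
    counts
        Genes x samples DataFrame (or CountMatrix) of non-negative
        integer counts; no normalization or log transform beforehand.
    batch
        Per-sample batch labels in column order, or a BatchDesign.
    covariates
        Optional samples x p numeric covariates whose effects are
        preserved through the adjustment.
    ref_batch
        If set, this batch's samples are returned bit-identical and the
        batch-free target is parameterized by this batch.

    Returns
    -------
    Adjusted integer count matrix with identical shape, ids and dtype.
    Genes with all-zero counts pass through unchanged.
    """
    cm = as_counts(counts)
    if isinstance(batch, BatchDesign):
        bd = batch
        if ref_batch is not None:
            bd = BatchDesign(bd.batch_of, bd.covariates, str(ref_batch))
    else:
        bd = BatchDesign.from_labels(
            cm.sample_ids, batch, covariates=covariates, ref_batch=ref_batch
        )
    design = validate_and_build_design(cm, bd, "count")

    Y = cm.values
    keep = Y.sum(axis=1) > 0
    sub = CountMatrix(cm.data.loc[np.asarray(cm.gene_ids)[keep]])

    dispersions = estimate_dispersions(sub, bd, design)
    fit = fit_nb_glm(sub, design, dispersions)
    plan = build_adjustment_plan(fit, dispersions, design)
    adj_sub = match_quantiles(sub, plan)

    out = cm.data.copy()
    out.loc[adj_sub.data.index] = adj_sub.data
    if design.ref_index is not None:
        ref_cols = [
            cm.sample_ids[j] for j in design.samples_of(design.ref_index)
        ]
        out[ref_cols] = cm.data[ref_cols]
    out = out.astype(cm.data.to_numpy().dtype)
    if isinstance(counts, CountMatrix):
        return CountMatrix(out)
    if isinstance(counts, pd.DataFrame):
        return out
    return CountMatrix(out)
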