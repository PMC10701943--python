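"""Empirical-Bayes location-scale batch correction for log-scale data.

The model for gene ``g``, sample ``j`` in batch ``i`` is

    y_gij = alpha_g + X_j beta_g + gamma_gi + delta_gi * eps_gij,

with eps ~ N(0, 1): each batch shifts the gene mean by ``gamma_gi`` and
scales its residual standard deviation by ``delta_gi``. Correction
proceeds in four steps:

1. standardize — per-gene least squares on the full design gives the
   baseline ``alpha_g`` (batch-size-weighted average of the batch
   coefficients), covariate effects and a pooled variance; residual
   z-scores carry the batch effects;
2. estimate hyperpriors — across genes, the per-batch location effects
   are moment-matched to a normal prior and the per-batch scale
   estimates to an inverse-gamma prior;
3. shrink — either the parametric coordinate-wise fixed-point iteration
   of the conditional posterior means, or the non-parametric weighting
   of every other gene's estimates by its likelihood;
4. adjust — remove the shrunk effects and restore the original scale
   and baseline.

With a reference batch, the baseline and pooled variance come from that
batch alone and its samples are passed through bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    BatchDesign,
    DesignMatrix,
    ExpressionMatrix,
    as_expression,
    validate_and_build_design,
)
from .errors import (
    ConvergenceWarning,
    DegenerateGeneWarning,
    EBDegenerateError,
    NumericalUnderflowWarning,
)

__all__ = [
    "NormalFit",
    "PriorHyperparams",
    "Posterior",
    "fit_standardization",
    "estimate_hyperpriors",
    "parametric_posterior",
    "nonparametric_posterior",
    "apply_adjustment",
    "pycombat_norm",
]


@dataclass
class NormalFit:
    """Standardization estimates for the location-scale model.

    ``gamma_hat`` and ``delta2_hat`` live on the standardized (z) scale;
    ``retained`` flags genes with positive pooled variance (constant
    genes bypass the EB machinery and are returned unchanged).
    """

    alpha: np.ndarray        # (G,) baseline
    beta: np.ndarray         # (G, p) covariate coefficients
    gamma_hat: np.ndarray    # (G, k) batch location effects, z scale
    sigma2: np.ndarray       # (G,) pooled variance
    z: np.ndarray            # (G, N) standardized data
    delta2_hat: np.ndarray   # (G, k) within-batch variances of z
    stand_mean: np.ndarray   # (G, N) alpha + X beta, broadcast per sample
    n_obs: np.ndarray        # (G, k) non-missing sample counts per batch
    retained: np.ndarray     # (G,) bool
    design: DesignMatrix


@dataclass
class PriorHyperparams:
    """Per-batch EB hyperparameters.

    Normal prior on the location effects (``gamma_bar``, ``tau2``) and
    inverse-gamma prior on the scale effects (shape ``lam``, scale
    ``theta``), both moment-matched across genes.
    """

    gamma_bar: np.ndarray  # (k,)
    tau2: np.ndarray       # (k,)
    lam: np.ndarray        # (k,) inverse-gamma shape
    theta: np.ndarray      # (k,) inverse-gamma scale


@dataclass
class Posterior:
    """Shrunk batch effects. ``iterations`` is parametric-only."""

    gamma_star: np.ndarray   # (G, k)
    delta2_star: np.ndarray  # (G, k)
    iterations: Optional[np.ndarray] = None


def _per_gene_ols(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for every gene; rows with NaN are
    dropped gene-wise. Returns (G, p)."""
    G, N = Y.shape
    p = X.shape[1]
    B = np.empty((G, p))
    finite = np.isfinite(Y)
    if finite.all():
        XtX = X.T @ X
        B[:] = np.linalg.solve(XtX, X.T @ Y.T).T
        return B
    complete = finite.all(axis=1)
    if complete.any():
        XtX = X.T @ X
        B[complete] = np.linalg.solve(XtX, X.T @ Y[complete].T).T
    for g in np.flatnonzero(~complete):
        m = finite[g]
        Xm = X[m]
        B[g] = np.linalg.lstsq(Xm, Y[g, m], rcond=None)[0]
    return B


def fit_standardization(
    matrix: ExpressionMatrix, design: DesignMatrix
) -> NormalFit:
    """Per-gene least squares and standardization.

    The pooled variance uses denominator N (non-missing count); the
    within-batch variances of z use ``n_i - 1``. With a reference batch
    the baseline is that batch's coefficient and the pooled variance is
    computed from the reference batch's residuals only.
    """
    Y = matrix.values.astype(float)
    X = design.matrix
    k = design.n_batches
    G, N = Y.shape
    finite = np.isfinite(Y)

    B = _per_gene_ols(Y, X)
    batch_coef = B[:, :k]
    beta = B[:, k:]

    sizes = design.batch_sizes.astype(float)
    if design.ref_index is None:
        alpha = batch_coef @ (sizes / sizes.sum())
    else:
        alpha = batch_coef[:, design.ref_index].copy()

    cov_term = beta @ design.covariate_part.T if beta.shape[1] else 0.0
    stand_mean = alpha[:, None] + cov_term

    resid = Y - (X @ B.T).T
    if design.ref_index is None:
        denom = finite.sum(axis=1)
        sigma2 = np.nansum(resid**2, axis=1) / denom
    else:
        ref_cols = design.samples_of(design.ref_index)
        denom = finite[:, ref_cols].sum(axis=1)
        with np.errstate(invalid="ignore"):
            sigma2 = np.nansum(resid[:, ref_cols] ** 2, axis=1) / denom

    retained = sigma2 > 0
    if not retained.all():
        n_const = int((~retained).sum())
        warnings.warn(
            f"{n_const} gene(s) with zero pooled variance bypass "
            f"correction and are returned unchanged",
            DegenerateGeneWarning,
            stacklevel=2,
        )

    sigma = np.sqrt(np.where(retained, sigma2, 1.0))
    with np.errstate(invalid="ignore"):
        z = (Y - stand_mean) / sigma[:, None]

    gamma_hat = np.zeros((G, k))
    delta2_hat = np.full((G, k), np.nan)
    n_obs = np.zeros((G, k))
    for i in range(k):
        cols = design.samples_of(i)
        zi = z[:, cols]
        ni = finite[:, cols].sum(axis=1)
        n_obs[:, i] = ni
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gamma_hat[:, i] = np.nanmean(zi, axis=1)
            delta2_hat[:, i] = np.nanvar(zi, axis=1, ddof=1)

    return NormalFit(
        alpha=alpha,
        beta=beta,
        gamma_hat=gamma_hat,
        sigma2=sigma2,
        z=z,
        delta2_hat=delta2_hat,
        stand_mean=np.broadcast_to(stand_mean, (G, N)).copy()
        if np.ndim(stand_mean) != 2 or stand_mean.shape != (G, N)
        else stand_mean,
        n_obs=n_obs,
        retained=retained,
        design=design,
    )


def estimate_hyperpriors(fit: NormalFit) -> PriorHyperparams:
    """Method-of-moments hyperparameters across retained genes.

    For each batch: ``gamma_bar`` / ``tau2`` are the across-gene mean
    and variance of the location estimates; the inverse-gamma shape and
    scale solve mean = theta/(lam-1), variance = theta^2/((lam-1)^2
    (lam-2)) for the across-gene moments (m, s2) of the scale
    estimates: lam = (m^2 + 2 s2)/s2, theta = (m s2 + m^3)/s2.
    """
    g = fit.gamma_hat[fit.retained]
    d = fit.delta2_hat[fit.retained]
    if g.shape[0] < 2:
        raise EBDegenerateError("need at least 2 retained genes")
    gamma_bar = g.mean(axis=0)
    tau2 = g.var(axis=0, ddof=1)
    m = np.nanmean(d, axis=0)
    s2 = np.nanvar(d, axis=0, ddof=1)
    if np.any(s2 == 0):
        raise EBDegenerateError(
            "across-gene variance of the scale estimates is zero; "
            "variance shrinkage is not identified"
        )
    lam = (m**2 + 2 * s2) / s2
    theta = (m * s2 + m**3) / s2
    return PriorHyperparams(gamma_bar=gamma_bar, tau2=tau2, lam=lam, theta=theta)


def parametric_posterior(
    fit: NormalFit,
    priors: PriorHyperparams,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> Posterior:
    """Iterate the conditional posterior means to a fixed point.

    Per gene and batch, alternate

        gamma* = (n tau2 gamma_hat + delta2* gamma_bar)
                 / (n tau2 + delta2*)
        delta2* = (theta + 0.5 sum_j (z_j - gamma*)^2)
                  / (n/2 + lam - 1)

    starting from (gamma_hat, delta2_hat), until the larger relative
    change of the two quantities drops below ``tol``. ``n`` is the
    non-missing sample count of the gene in the batch.
    """
    G, k = fit.gamma_hat.shape
    gamma_star = fit.gamma_hat.copy()
    delta2_star = fit.delta2_hat.copy()
    iterations = np.zeros((G, k), dtype=np.int64)
    retained = fit.retained
    hit_cap = False

    for i in range(k):
        cols = fit.design.samples_of(i)
        zi = fit.z[retained][:, cols]
        n = fit.n_obs[retained, i]
        ghat = fit.gamma_hat[retained, i]
        g_old = ghat.copy()
        d_old = fit.delta2_hat[retained, i].copy()
        tau2, gbar = priors.tau2[i], priors.gamma_bar[i]
        lam, theta = priors.lam[i], priors.theta[i]
        m = g_old.size
        active = np.ones(m, dtype=bool)
        iters = np.zeros(m, dtype=np.int64)
        g_cur, d_cur = g_old, d_old
        for _ in range(max_iter):
            if not active.any():
                break
            ga, da = g_cur[active], d_cur[active]
            g_new = (n[active] * tau2 * ghat[active] + da * gbar) / (
                n[active] * tau2 + da
            )
            sum2 = np.nansum((zi[active] - g_new[:, None]) ** 2, axis=1)
            d_new = (theta + 0.5 * sum2) / (n[active] / 2 + lam - 1)
            change = np.maximum(
                np.abs(g_new - ga) / np.maximum(np.abs(ga), 1e-30),
                np.abs(d_new - da) / np.maximum(np.abs(da), 1e-30),
            )
            g_cur = g_cur.copy()
            d_cur = d_cur.copy()
            g_cur[active] = g_new
            d_cur[active] = d_new
            iters[active] += 1
            still = change >= tol
            idx = np.flatnonzero(active)
            active[idx[~still]] = False
        else:
            hit_cap = hit_cap or active.any()
        gamma_star[retained, i] = g_cur
        delta2_star[retained, i] = d_cur
        iterations[retained, i] = iters

    if hit_cap:
        warnings.warn(
            f"parametric posterior hit max_iter={max_iter} for some "
            f"genes; last iterate returned",
            ConvergenceWarning,
            stacklevel=2,
        )
    return Posterior(
        gamma_star=gamma_star, delta2_star=delta2_star, iterations=iterations
    )


def nonparametric_posterior(fit: NormalFit) -> Posterior:
    """Shrink each gene's batch effects toward the other genes'.

    For gene g in batch i every other retained gene g' acts as a donor
    with weight proportional to the likelihood of g's standardized
    values under N(gamma_hat_g'i, delta2_hat_g'i); the posterior is the
    weighted average of the donors' (gamma_hat, delta2_hat). Weights
    are accumulated in log space with max subtraction.
    """
    G, k = fit.gamma_hat.shape
    gamma_star = fit.gamma_hat.copy()
    delta2_star = fit.delta2_hat.copy()
    ridx = np.flatnonzero(fit.retained)
    m = ridx.size
    if m < 2:
        raise EBDegenerateError("need at least 2 retained genes")
    underflow = 0

    for i in range(k):
        cols = fit.design.samples_of(i)
        Z = fit.z[ridx][:, cols]          # (m, n_i)
        g = fit.gamma_hat[ridx, i]        # (m,)
        d = fit.delta2_hat[ridx, i]       # (m,)
        finite = np.isfinite(Z)
        log_norm = np.log(2 * np.pi * d)  # (m,) per-donor constant term
        gs = np.empty(m)
        ds = np.empty(m)
        for a in range(m):
            zrow = Z[a]
            mask = finite[a]
            za = zrow[mask]
            # log-likelihood of gene a's samples under every donor
            diff = za[None, :] - g[:, None]
            logw = -0.5 * (
                np.sum(diff**2, axis=1) / d + mask.sum() * log_norm
            )
            logw[a] = -np.inf
            top = np.max(logw)
            if not np.isfinite(top):
                underflow += 1
                gs[a], ds[a] = g[a], d[a]
                continue
            w = np.exp(logw - top)
            w /= w.sum()
            gs[a] = w @ g
            ds[a] = w @ d
        gamma_star[ridx, i] = gs
        delta2_star[ridx, i] = ds

    if underflow:
        warnings.warn(
            f"donor weights underflowed for {underflow} gene-batch "
            f"pairs; own estimates kept",
            NumericalUnderflowWarning,
            stacklevel=2,
        )
    return Posterior(gamma_star=gamma_star, delta2_star=delta2_star)


def apply_adjustment(
    fit: NormalFit,
    post: Posterior,
    design: Optional[DesignMatrix] = None,
    original: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Invert the model with the shrunk effects:

        y*_gij = (sigma_g / delta*_gi) (z_gij - gamma*_gi)
                 + alpha_g + X_j beta_g.

    Gene-batch cells whose posterior is exactly the identity transform
    (gamma* = 0 and delta2* = 1) are passed through unchanged, so a
    no-op posterior reproduces the input bit for bit. Constant genes
    and reference-batch samples are likewise passed through. ``original``
    defaults to reconstructing the input from the stored z-scores.
    """
    design = design if design is not None else fit.design
    G, N = fit.z.shape
    sigma = np.sqrt(np.where(fit.retained, fit.sigma2, 1.0))
    if original is None:
        original = fit.z * sigma[:, None] + fit.stand_mean

    out = np.array(original, dtype=float, copy=True)
    for i in range(design.n_batches):
        cols = design.samples_of(i)
        if design.ref_index is not None and i == design.ref_index:
            continue
        gamma = post.gamma_star[:, i]
        delta = np.sqrt(post.delta2_star[:, i])
        identity = (gamma == 0.0) & (post.delta2_star[:, i] == 1.0)
        rows = fit.retained & ~identity
        if not rows.any():
            continue
        adj = (
            sigma[rows, None] / delta[rows, None]
        ) * (fit.z[rows][:, cols] - gamma[rows, None]) + fit.stand_mean[rows][
            :, cols
        ]
        out[np.ix_(rows, cols)] = adj
    return out


def pycombat_norm(
    matrix,
    batch,
    covariates: Optional[pd.DataFrame] = None,
    method: str = "parametric",
    mean_only: bool = False,
    ref_batch: Optional[str] = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
):
    """Correct batch effects in a log-scale expression matrix.

    Parameters
    ----------
    matrix
        Genes x samples DataFrame (or ExpressionMatrix) of log-scale
        values, e.g. RMA-normalized microarray intensities.
    batch
        Per-sample batch labels, in the matrix's column order, or a
        prebuilt :class:`BatchDesign`.
    covariates
        Optional samples x p numeric table of covariates to protect.
    method
        ``"parametric"`` (fast, assumes normal/inverse-gamma priors) or
        ``"nonparametric"`` (prior-free, slower).
    mean_only
        Adjust only the batch means, leaving per-batch variances alone.
    ref_batch
        If set, samples of this batch are returned unchanged and all
        other batches are adjusted toward its distribution.

    Returns
    -------
    Corrected matrix with the input's gene/sample order; a DataFrame is
    returned when a DataFrame was passed.
    """
    if method not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown method {method!r}")
    expr = as_expression(matrix)
    if isinstance(batch, BatchDesign):
        bd = batch
        if ref_batch is not None:
            bd = BatchDesign(bd.batch_of, bd.covariates, str(ref_batch))
    else:
        bd = BatchDesign.from_labels(
            expr.sample_ids, batch, covariates=covariates, ref_batch=ref_batch
        )
    design = validate_and_build_design(expr, bd, "normal", mean_only=mean_only)

    fit = fit_standardization(expr, design)
    if mean_only:
        # scale estimates never enter a location-only adjustment
        fit.delta2_hat = np.ones_like(fit.delta2_hat)

    if method == "parametric" and mean_only:
        # location-only shrinkage at unit variance: closed form, no
        # fixed-point iteration needed
        g = fit.gamma_hat[fit.retained]
        gamma_bar = g.mean(axis=0)
        tau2 = g.var(axis=0, ddof=1)
        gamma_star = fit.gamma_hat.copy()
        gamma_star[fit.retained] = (tau2[None, :] * g + gamma_bar[None, :]) / (
            tau2[None, :] + 1.0
        )
        post = Posterior(
            gamma_star=gamma_star,
            delta2_star=np.ones_like(fit.delta2_hat),
        )
    elif method == "parametric":
        try:
            priors = estimate_hyperpriors(fit)
            post = parametric_posterior(fit, priors, tol=tol, max_iter=max_iter)
        except EBDegenerateError:
            # all scale estimates identical: shrink locations only
            g = fit.gamma_hat[fit.retained]
            gamma_bar = g.mean(axis=0)
            tau2 = g.var(axis=0, ddof=1)
            gamma_star = fit.gamma_hat.copy()
            n = fit.n_obs
            d = fit.delta2_hat
            num = n * tau2[None, :] * fit.gamma_hat + d * gamma_bar[None, :]
            den = n * tau2[None, :] + d
            gamma_star[fit.retained] = (num / den)[fit.retained]
            post = Posterior(
                gamma_star=gamma_star,
                delta2_star=np.ones_like(d) if mean_only else d.copy(),
            )
    else:
        post = nonparametric_posterior(fit)
        if mean_only:
            post.delta2_star = np.ones_like(post.delta2_star)

    adjusted = apply_adjustment(fit, post, design, original=expr.values)
    out = pd.DataFrame(
        adjusted, index=expr.gene_ids, columns=expr.sample_ids
    )
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(out)
    return out
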