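"""Negative-binomial GLM machinery for the count corrector.

Counts are modelled as y_gij ~ NB(mu_gij, phi_gi) with log link,

    log mu_gij = alpha_g + X_j beta_g + gamma_gi + offset_j,

Var(y) = mu + phi mu^2, and per-sample offsets equal to the log raw
library sizes (column sums). Dispersions are estimated per batch by
maximizing the Cox-Reid adjusted profile likelihood (APL): the NB
log-likelihood at the fitted coefficients minus half the log
determinant of the Fisher information, which removes the downward bias
of plugging in fitted means. A batch-common value is found by a coarse
log-spaced grid plus golden-section refinement; gene-wise values are
refined the same way when the batch is large enough, seeded by the
common value and a method-of-moments candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data_model import BatchDesign, CountMatrix, DesignMatrix
from .errors import IRLSDivergenceWarning, PoissonFallbackWarning

__all__ = ["DispersionEstimates", "NBFit", "estimate_dispersions", "fit_nb_glm"]

_PHI_LO = 1e-6
_PHI_HI = 10.0
_MU_FLOOR = 1e-8
_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class DispersionEstimates:
    """Per-gene-per-batch dispersions phi_gi with common fallbacks."""

    genewise: np.ndarray      # (G, k)
    common: np.ndarray        # (k,)
    method_used: list         # per batch: "genewise" or "common"
    batches: list


@dataclass
class NBFit:
    """Per-gene NB GLM coefficients and fitted means."""

    coefficients: np.ndarray  # (G, p) matching DesignMatrix columns
    offsets: np.ndarray       # (N,) log library sizes
    fitted_mu: np.ndarray     # (G, N)
    converged: np.ndarray     # (G,) bool


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log pmf; phi per gene (phi=0 -> Poisson)."""
    mu = np.maximum(mu, _MU_FLOOR)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(Y.shape[0])
    pois = phi <= 0
    if pois.any():
        Yp, mup = Y[pois], mu[pois]
        out[pois] = np.sum(Yp * np.log(mup) - mup - gammaln(Yp + 1), axis=1)
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb, None]
        Yn, mun = Y[nb], mu[nb]
        out[nb] = np.sum(
            gammaln(Yn + r)
            - gammaln(r)
            - gammaln(Yn + 1)
            + r * np.log(r / (r + mun))
            + Yn * np.log(mun / (r + mun)),
            axis=1,
        )
    return out


def _irls(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray,
    beta0: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene IRLS with fixed dispersion.

    ``phi`` may be scalar, per-gene (G,), or per-gene-per-sample (G, N).
    Returns (beta, mu, converged). Linear predictors are clipped to
    keep mu in (exp(-30), exp(30)) times the offset scale.
    """
    G, N = Y.shape
    p = X.shape[1]
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi_mat = np.full((G, N), float(phi))
    elif phi.ndim == 1:
        phi_mat = np.broadcast_to(phi[:, None], (G, N))
    else:
        phi_mat = phi
    beta = beta0.copy()
    eta = beta @ X.T + offsets[None, :]
    mu = np.exp(np.clip(eta - offsets[None, :], -30, 30) + offsets[None, :])
    mu = np.maximum(mu, _MU_FLOOR)
    dev = _deviance(Y, mu, phi_mat)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        mua = mu[idx]
        W = mua / (1.0 + phi_mat[idx] * mua)
        # working response on the linear-predictor scale, minus offset
        zw = (beta[idx] @ X.T) + (Y[idx] - mua) / mua
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
        XtWz = np.einsum("np,gn,gn->gp", X, W, zw)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.stack(
                [
                    np.linalg.lstsq(XtWX[j], XtWz[j], rcond=None)[0]
                    for j in range(idx.size)
                ]
            )
        bad = ~np.isfinite(new_beta).all(axis=1)
        new_beta[bad] = beta[idx][bad]
        beta[idx] = new_beta
        lin = np.clip(new_beta @ X.T, -30, 30)
        mu[idx] = np.maximum(np.exp(lin + offsets[None, :]), _MU_FLOOR)
        new_dev = _deviance(Y[idx], mu[idx], phi_mat[idx])
        done = np.abs(new_dev - dev[idx]) < tol * np.maximum(
            1.0, np.abs(new_dev)
        )
        done |= bad
        dev[idx] = new_dev
        converged[idx[done]] = True
        active[idx[done]] = False
    return beta, mu, converged


def _deviance(Y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, _MU_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(Y > 0, Y * np.log(np.maximum(Y, 1) / mu), 0.0)
        pois_part = 2.0 * (ylogy - (Y - mu))
        r = np.where(phi > 0, 1.0 / np.maximum(phi, 1e-300), np.inf)
        nb_part = 2.0 * (
            ylogy
            - np.where(
                phi > 0,
                (Y + r) * np.log((Y + r) / (mu + r)),
                Y - mu,
            )
        )
    return np.sum(np.where(phi > 0, nb_part, pois_part), axis=1)


def _init_beta(
    Y: np.ndarray, X: np.ndarray, offsets: np.ndarray, n_indicator: int
) -> np.ndarray:
    """Start values: per indicator column the mean of log((y+0.1)/lib)
    over that column's samples; covariate coefficients start at 0."""
    G = Y.shape[0]
    p = X.shape[1]
    beta0 = np.zeros((G, p))
    logy = np.log(Y + 0.1) - offsets[None, :]
    for c in range(n_indicator):
        cols = np.flatnonzero(X[:, c] != 0)
        beta0[:, c] = logy[:, cols].mean(axis=1)
    return beta0


def _apl(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray,
    beta0: np.ndarray,
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at phi."""
    beta, mu, _ = _irls(Y, X, offsets, phi, beta0, max_iter=25, tol=1e-6)
    ll = _nb_loglik(Y, mu, np.broadcast_to(phi, (Y.shape[0],)))
    phi_col = np.broadcast_to(
        np.asarray(phi, dtype=float).reshape(-1, 1), mu.shape
    ) if np.ndim(phi) else np.full_like(mu, float(phi))
    W = mu / (1.0 + phi_col * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
    sign, logdet = np.linalg.slogdet(
        XtWX + 1e-12 * np.eye(X.shape[1])[None, :, :]
    )
    return ll - 0.5 * logdet


def _golden_max(
    f, lo: np.ndarray, hi: np.ndarray, n_iter: int = 30
) -> np.ndarray:
    """Vectorized golden-section maximization of f over per-gene
    log-scale brackets [lo, hi] (phi units). Returns argmax."""
    a = np.log(lo)
    b = np.log(hi)
    for _ in range(n_iter):
        x1 = b - _GOLD * (b - a)
        x2 = a + _GOLD * (b - a)
        f1 = f(np.exp(x1))
        f2 = f(np.exp(x2))
        take1 = f1 >= f2
        b = np.where(take1, x2, b)
        a = np.where(take1, a, x1)
    return np.exp((a + b) / 2.0)


def _mom_dispersion(Y: np.ndarray) -> np.ndarray:
    """max(0, (v - m)/m^2) per gene, v the sample variance."""
    m = Y.mean(axis=1)
    v = Y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (v - m) / np.maximum(m, 1e-300) ** 2
    return np.where(m > 0, np.maximum(mom, 0.0), 0.0)


def estimate_dispersions(
    counts: CountMatrix,
    batches: BatchDesign,
    design: DesignMatrix,
) -> DispersionEstimates:
    """Per-batch NB dispersions by Cox-Reid APL maximization.

    For each batch the within-batch design is an intercept plus the
    covariate columns. A batch-common dispersion maximizes the summed
    APL over a log grid on [1e-6, 10] with golden-section refinement;
    when the optimum sits at the lower bound the batch is flagged as
    Poisson (common = 0). Gene-wise dispersions are refined per gene
    when the batch holds more than (covariate columns + 2) samples,
    otherwise the common value is used.
    """
    Y_all = counts.values.astype(float)
    offsets_all = np.log(Y_all.sum(axis=0))
    k = design.n_batches
    G = Y_all.shape[0]
    p_cov = design.covariate_part.shape[1]
    genewise = np.zeros((G, k))
    common = np.zeros(k)
    method_used = []

    for i in range(k):
        cols = design.samples_of(i)
        Y = Y_all[:, cols]
        offs = offsets_all[cols]
        Xi = np.hstack(
            [np.ones((cols.size, 1)), design.covariate_part[cols]]
        )
        beta0 = _init_beta(Y, Xi, offs, 1)
        nonzero = Y.sum(axis=1) > 0

        def batch_apl(phi_vec: np.ndarray) -> np.ndarray:
            phi_full = np.zeros(G)
            phi_full[nonzero] = (
                phi_vec[nonzero] if phi_vec.ndim else phi_vec
            )
            out = np.full(G, 0.0)
            out[nonzero] = _apl(
                Y[nonzero], Xi, offs, phi_full[nonzero], beta0[nonzero]
            )
            return out

        # common dispersion: grid then golden-section on total APL
        grid = np.geomspace(_PHI_LO, _PHI_HI, 9)
        totals = np.array(
            [batch_apl(np.full(G, g0)).sum() for g0 in grid]
        )
        best = int(np.argmax(totals))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid.size - 1)]
        if best == 0:
            lo = _PHI_LO
        phi_c = float(
            _golden_max(
                lambda ph: batch_apl(np.full(G, float(ph[0]))).sum()
                * np.ones(1),
                np.array([lo]),
                np.array([hi]),
            )[0]
        )
        if best == 0 and phi_c < 3 * _PHI_LO:
            warnings.warn(
                f"batch {design.batches[i]!r}: dispersion profile "
                f"likelihood maximized at the lower bound; treating "
                f"counts as Poisson",
                PoissonFallbackWarning,
                stacklevel=2,
            )
            common[i] = 0.0
            genewise[:, i] = 0.0
            method_used.append("common")
            continue
        common[i] = phi_c

        if cols.size > p_cov + 2:
            # gene-wise refinement seeded by common and MOM candidates
            mom = np.clip(_mom_dispersion(Y), _PHI_LO, _PHI_HI)
            cand = np.column_stack(
                [
                    np.full(G, _PHI_LO),
                    np.full(G, phi_c),
                    mom,
                    np.full(G, _PHI_HI),
                    np.sqrt(phi_c * mom),
                ]
            )
            extra = np.geomspace(_PHI_LO * 10, _PHI_HI / 10, 4)
            cand = np.hstack([cand, np.broadcast_to(extra, (G, 4))])
            cand = np.sort(cand, axis=1)
            scores = np.stack(
                [batch_apl(cand[:, c]) for c in range(cand.shape[1])],
                axis=1,
            )
            best_c = np.argmax(scores, axis=1)
            lo_g = cand[np.arange(G), np.maximum(best_c - 1, 0)]
            hi_g = cand[
                np.arange(G), np.minimum(best_c + 1, cand.shape[1] - 1)
            ]
            at_lb = best_c == 0
            lo_g[at_lb] = _PHI_LO
            phi_g = _golden_max(batch_apl, lo_g, hi_g)
            phi_g = np.where(phi_g < 3 * _PHI_LO, 0.0, phi_g)
            phi_g[~nonzero] = common[i]
            genewise[:, i] = phi_g
            method_used.append("genewise")
        else:
            genewise[:, i] = common[i]
            method_used.append("common")

    return DispersionEstimates(
        genewise=genewise,
        common=common,
        method_used=method_used,
        batches=list(design.batches),
    )


def fit_nb_glm(
    counts: CountMatrix,
    design: DesignMatrix,
    dispersions: DispersionEstimates,
) -> NBFit:
    """Per-gene NB regression on the full design with fixed dispersions.

    Offsets are the log column sums. Each sample's dispersion is its
    batch's gene-wise value. Genes whose IRLS diverges fall back to
    method-of-moments coefficients (log batch means net of the mean
    offset) with a warning.
    """
    Y = counts.values.astype(float)
    G, N = Y.shape
    X = design.matrix
    offsets = np.log(Y.sum(axis=0))
    phi_mat = dispersions.genewise[:, design.batch_index]  # (G, N)
    beta0 = _init_beta(Y, X, offsets, design.n_batches)
    beta, mu, converged = _irls(Y, X, offsets, phi_mat, beta0)

    if not converged.all():
        bad = np.flatnonzero(~converged)
        warnings.warn(
            f"IRLS did not converge for {bad.size} gene(s); "
            f"method-of-moments coefficients used",
            IRLSDivergenceWarning,
            stacklevel=2,
        )
        mean_off = offsets.mean()
        for g in bad:
            coef = np.zeros(X.shape[1])
            for i in range(design.n_batches):
                cols = design.samples_of(i)
                coef[i] = np.log(Y[g, cols].mean() + 0.1) - mean_off
            beta[g] = coef
        mu[bad] = np.maximum(
            np.exp(np.clip(beta[bad] @ X.T, -30, 30) + offsets[None, :]),
            _MU_FLOOR,
        )

    return NBFit(
        coefficients=beta, offsets=offsets, fitted_mu=mu, converged=converged
    )
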