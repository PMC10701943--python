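"""Simulators with known batch and covariate structure.

Both generators draw forward from the corrector models, so every
injected effect is recorded and recoverable: the microarray generator
from the normal location-scale model (additive batch shifts gamma_gi,
multiplicative residual scales delta_gi), the count generator from the
NB model (per-batch mean fold changes, common dispersion, per-sample
library-size factors). A single integer seed drives one Generator
instance per call, so identical calls are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import BatchDesign, CountMatrix, ExpressionMatrix

__all__ = ["SimTruth", "simulate_microarray", "simulate_counts"]


@dataclass
class SimTruth:
    """Ground-truth effects injected by a simulator."""

    gamma_true: Optional[np.ndarray] = None   # (G, k) additive shifts
    delta2_true: Optional[np.ndarray] = None  # (G, k) variance factors
    fold_true: Optional[np.ndarray] = None    # (G, k) mean multipliers
    phi_true: Optional[float] = None
    beta_true: Optional[np.ndarray] = None    # (G,) covariate effect
    cov_genes: Optional[np.ndarray] = None    # bool mask of affected genes
    affected_genes: Optional[np.ndarray] = None  # bool mask (fold change)
    lib_factors: Optional[np.ndarray] = None  # (N,)
    seed: int = 0


def _labels(batch_sizes: Sequence[int]) -> tuple[list, list]:
    sample_ids, batch_labels = [], []
    for i, n in enumerate(batch_sizes):
        for j in range(n):
            sample_ids.append(f"s{i + 1}_{j + 1}")
            batch_labels.append(f"batch{i + 1}")
    return sample_ids, batch_labels


def _binary_covariate(
    batch_sizes: Sequence[int], rng: np.random.Generator
) -> np.ndarray:
    """Balanced two-group indicator within every batch, so the
    covariate is never confounded with batch."""
    parts = []
    for n in batch_sizes:
        v = np.zeros(n)
        v[: n // 2] = 1.0
        rng.shuffle(v)
        parts.append(v)
    return np.concatenate(parts)


def simulate_microarray(
    n_genes: int = 1000,
    batch_sizes: Sequence[int] = (20, 20),
    gamma_spread: float = 1.0,
    delta_shape: float = 4.0,
    beta_true: Optional[float] = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, BatchDesign, SimTruth]:
    """Log-scale expression with injected location-scale batch effects.

    Baselines alpha_g ~ N(8, 2); per-gene batch shifts gamma_gi ~
    N(0, gamma_spread^2), recentered so the batch-size-weighted shifts
    sum to zero per gene; residual variance factors delta2_gi ~
    inverse-gamma(delta_shape, delta_shape - 1), mean 1. If
    ``beta_true`` is set, a balanced binary covariate shifts a random
    half of the genes by that amount.
    """
    if len(batch_sizes) < 2:
        raise ValueError("need at least 2 batches")
    if gamma_spread < 0 or delta_shape <= 2:
        raise ValueError("gamma_spread >= 0 and delta_shape > 2 required")
    rng = np.random.default_rng(seed)
    k = len(batch_sizes)
    N = int(sum(batch_sizes))
    sizes = np.asarray(batch_sizes, dtype=float)
    w = sizes / sizes.sum()

    alpha = rng.normal(8.0, 2.0, size=n_genes)
    gamma = rng.normal(0.0, gamma_spread, size=(n_genes, k))
    gamma -= (gamma @ w)[:, None]  # weighted-zero constraint
    delta2 = 1.0 / rng.gamma(
        delta_shape, 1.0 / (delta_shape - 1.0), size=(n_genes, k)
    )

    sample_ids, batch_labels = _labels(batch_sizes)
    batch_index = np.repeat(np.arange(k), batch_sizes)

    cov = None
    beta_vec = None
    cov_genes = None
    if beta_true is not None:
        x = _binary_covariate(batch_sizes, rng)
        cov = pd.DataFrame({"group": x}, index=sample_ids)
        cov_genes = np.zeros(n_genes, dtype=bool)
        cov_genes[rng.permutation(n_genes)[: n_genes // 2]] = True
        beta_vec = np.where(cov_genes, float(beta_true), 0.0)

    eps = rng.normal(size=(n_genes, N))
    y = (
        alpha[:, None]
        + gamma[:, batch_index]
        + np.sqrt(delta2[:, batch_index]) * eps
    )
    if beta_vec is not None:
        y = y + beta_vec[:, None] * cov["group"].to_numpy()[None, :]

    expr = ExpressionMatrix(
        pd.DataFrame(
            y,
            index=[f"g{i + 1}" for i in range(n_genes)],
            columns=sample_ids,
        )
    )
    bd = BatchDesign.from_labels(sample_ids, batch_labels, covariates=cov)
    truth = SimTruth(
        gamma_true=gamma,
        delta2_true=delta2,
        beta_true=beta_vec,
        cov_genes=cov_genes,
        seed=seed,
    )
    return expr, bd, truth


def simulate_counts(
    n_genes: int = 2000,
    batch_sizes: Sequence[int] = (15, 15),
    fold_change: float = 2.0,
    phi_true: float = 0.3,
    lib_size_range: tuple[float, float] = (0.7, 1.4),
    beta_true: Optional[float] = None,
    affected_fraction: float = 0.5,
    base_mean: float = 50.0,
    seed: int = 0,
) -> tuple[CountMatrix, BatchDesign, SimTruth]:
    """Raw NB counts with an injected per-batch mean fold change.

    Per-gene base means are log-normal (median ``base_mean``, sdlog 1).
    Every batch after the first multiplies the means of a random
    ``affected_fraction`` of genes by ``fold_change``. Per-sample
    library factors are uniform on ``lib_size_range`` and scale the
    means multiplicatively. Counts ~ NB(mean, phi_true); phi_true = 0
    draws Poisson. If ``beta_true`` is set, a balanced binary covariate
    multiplies a random half of the genes by exp(beta_true).
    """
    if len(batch_sizes) < 2:
        raise ValueError("need at least 2 batches")
    if fold_change <= 0 or phi_true < 0:
        raise ValueError("fold_change > 0 and phi_true >= 0 required")
    rng = np.random.default_rng(seed)
    k = len(batch_sizes)
    N = int(sum(batch_sizes))
    batch_index = np.repeat(np.arange(k), batch_sizes)

    base = np.exp(rng.normal(np.log(base_mean), 1.0, size=n_genes))
    affected = np.zeros(n_genes, dtype=bool)
    affected[rng.permutation(n_genes)[: int(round(affected_fraction * n_genes))]] = True
    fold = np.ones((n_genes, k))
    fold[affected, 1:] = fold_change

    sample_ids, batch_labels = _labels(batch_sizes)
    cov = None
    beta_vec = None
    cov_genes = None
    if beta_true is not None:
        x = _binary_covariate(batch_sizes, rng)
        cov = pd.DataFrame({"group": x}, index=sample_ids)
        cov_genes = np.zeros(n_genes, dtype=bool)
        cov_genes[rng.permutation(n_genes)[: n_genes // 2]] = True
        beta_vec = np.where(cov_genes, float(beta_true), 0.0)

    lib = rng.uniform(lib_size_range[0], lib_size_range[1], size=N)
    mu = base[:, None] * fold[:, batch_index] * lib[None, :]
    if beta_vec is not None:
        mu = mu * np.exp(
            beta_vec[:, None] * cov["group"].to_numpy()[None, :]
        )

    if phi_true == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi_true
        counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(
        pd.DataFrame(
            counts.astype(np.int64),
            index=[f"g{i + 1}" for i in range(n_genes)],
            columns=sample_ids,
        )
    )
    bd = BatchDesign.from_labels(sample_ids, batch_labels, covariates=cov)
    truth = SimTruth(
        fold_true=fold,
        phi_true=phi_true,
        beta_true=beta_vec,
        cov_genes=cov_genes,
        affected_genes=affected,
        lib_factors=lib,
        seed=seed,
    )
    return cm, bd, truth
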