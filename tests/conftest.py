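from pathlib import Path

import numpy as np
import pandas as pd
import pytest

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_expression():
    """12x10 log-scale fixture with 3 batches and one covariate."""
    expr = pd.read_csv(DATA / "toy_expr.tsv", sep="\t", index_col=0)
    bt = pd.read_csv(DATA / "toy_batch.tsv", sep="\t")
    cov = pd.read_csv(DATA / "toy_cov.tsv", sep="\t", index_col=0)
    return expr, bt["batch"].tolist(), cov


@pytest.fixture(scope="session")
def small_counts():
    """Deterministic small NB count matrix with 2 batches."""
    rng = np.random.default_rng(5)
    G, n = 40, 6
    mu = np.exp(rng.normal(3.0, 1.0, size=(G, 1)))
    shift = np.where(rng.random(G) < 0.5, 2.0, 1.0)
    means = np.hstack([np.tile(mu, n), np.tile(mu * shift[:, None], n)])
    r = 1 / 0.2
    counts = rng.negative_binomial(r, r / (r + means))
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(G)],
        columns=[f"s{j}" for j in range(2 * n)],
    )
    return df, ["A"] * n + ["B"] * n


def sva_reference(name: str) -> pd.DataFrame:
    """Frozen output of the standard R implementation (sva) on the toy
    fixture, used as an independent regression oracle."""
    return pd.read_csv(DATA / name, sep="\t", index_col=0)
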