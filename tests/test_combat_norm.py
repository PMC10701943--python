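import numpy as np
import pandas as pd
import pytest

from ebatch import (
    BatchDesign,
    ExpressionMatrix,
    Posterior,
    apply_adjustment,
    estimate_hyperpriors,
    fit_standardization,
    nonparametric_posterior,
    parametric_posterior,
    pycombat_norm,
    simulate_microarray,
    validate_and_build_design,
)
from ebatch.errors import DegenerateGeneWarning, SingleBatchError

from conftest import sva_reference


def _fit(values, labels, covariates=None, ref_batch=None, n_genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    em = ExpressionMatrix(df)
    bd = BatchDesign.from_labels(
        em.sample_ids, labels, covariates=covariates, ref_batch=ref_batch
    )
    design = validate_and_build_design(em, bd)
    return em, fit_standardization(em, design)


class TestStandardization:
    def test_closed_form_two_batch_example(self):
        """y=[0,2,4,6], batches AABB: weighted baseline 3, batch
        effects -2/+2, pooled variance 1, z=[-3,-1,1,3]."""
        _, fit = _fit([[0, 2, 4, 6], [1, 2, 3, 4]], ["A", "A", "B", "B"])
        assert fit.alpha[0] == pytest.approx(3.0)
        np.testing.assert_allclose(fit.gamma_hat[0], [-2.0, 2.0])
        assert fit.sigma2[0] == pytest.approx(1.0)
        np.testing.assert_allclose(fit.z[0], [-3, -1, 1, 3])

    def test_identical_batches_give_zero_gamma(self):
        _, fit = _fit(
            [[1, 5, 1, 5], [2, 7, 2, 7]], ["A", "A", "B", "B"]
        )
        np.testing.assert_allclose(fit.gamma_hat, 0.0, atol=1e-12)

    def test_weighted_gamma_constraint(self):
        rng = np.random.default_rng(1)
        y = rng.normal(8, 2, size=(50, 9))
        labels = ["A"] * 2 + ["B"] * 3 + ["C"] * 4
        _, fit = _fit(y, labels)
        n = np.array([2, 3, 4]) / 9
        np.testing.assert_allclose(fit.gamma_hat @ n, 0.0, atol=1e-8)

    def test_reference_batch_parametrization(self):
        """With ref_batch=A the baseline is A's own least-squares batch
        mean, gamma_hat of A is 0 and the pooled variance comes from
        A's residuals only (direct least-squares oracle)."""
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, size=(5, 8)) + np.repeat([1.0, 4.0], 4)[None, :]
        labels = ["A"] * 4 + ["B"] * 4
        _, fit = _fit(y, labels, ref_batch="A")
        np.testing.assert_allclose(fit.alpha, y[:, :4].mean(axis=1))
        np.testing.assert_allclose(fit.gamma_hat[:, 0], 0.0, atol=1e-12)
        resid_a = y[:, :4] - y[:, :4].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(fit.sigma2, (resid_a**2).sum(axis=1) / 4)

    def test_constant_gene_flagged(self):
        with pytest.warns(DegenerateGeneWarning):
            _, fit = _fit(
                [[3, 3, 3, 3], [0, 2, 4, 6]], ["A", "A", "B", "B"]
            )
        assert not fit.retained[0] and fit.retained[1]

    def test_missing_values_ignored_in_moments(self):
        y = np.array([[0, 2, np.nan, 4, 6, np.nan]])
        _, fit = _fit(
            np.vstack([y, [[1, 2, 3, 2, 3, 4]]]),
            ["A", "A", "A", "B", "B", "B"],
        )
        # per-batch means of gene 0 use only observed entries
        assert fit.n_obs[0].tolist() == [2, 2]
        assert fit.alpha[0] == pytest.approx(3.0)


class TestHyperpriors:
    def test_two_point_location_moments(self):
        _, fit = _fit(
            [[0, 2, 4, 6], [1, 2, 3, 4]], ["A", "A", "B", "B"]
        )
        fit.gamma_hat = np.array([[-0.5, -0.5], [0.5, 0.5]])
        fit.delta2_hat = np.array([[1.0, 1.0], [3.0, 3.0]])
        pri = estimate_hyperpriors(fit)
        np.testing.assert_allclose(pri.gamma_bar, [0.0, 0.0])
        np.testing.assert_allclose(pri.tau2, [0.5, 0.5])

    def test_inverse_gamma_moment_matching(self):
        """delta2 over genes = [1, 3]: m=2, s2=2 give shape 4, scale 6;
        an inverse-gamma(4, 6) indeed has mean 2 and variance 2."""
        _, fit = _fit(
            [[0, 2, 4, 6], [1, 2, 3, 4]], ["A", "A", "B", "B"]
        )
        fit.delta2_hat = np.array([[1.0, 1.0], [3.0, 3.0]])
        pri = estimate_hyperpriors(fit)
        np.testing.assert_allclose(pri.lam, [4.0, 4.0])
        np.testing.assert_allclose(pri.theta, [6.0, 6.0])
        mean = pri.theta / (pri.lam - 1)
        var = pri.theta**2 / ((pri.lam - 1) ** 2 * (pri.lam - 2))
        np.testing.assert_allclose(mean, [2.0, 2.0])
        np.testing.assert_allclose(var, [2.0, 2.0])


class TestParametricPosterior:
    def test_hand_iteration_first_step(self):
        """n=2, z=[1,3], gamma_hat=2, delta2_hat=2, priors (0,1,3,2):
        first update gives gamma*=1, then delta2*=4/3."""
        n, tau2, gbar, lam, theta = 2, 1.0, 0.0, 3.0, 2.0
        ghat, d_old = 2.0, 2.0
        z = np.array([1.0, 3.0])
        g1 = (n * tau2 * ghat + d_old * gbar) / (n * tau2 + d_old)
        assert g1 == pytest.approx(1.0)
        d1 = (theta + 0.5 * np.sum((z - g1) ** 2)) / (n / 2 + lam - 1)
        assert d1 == pytest.approx(4.0 / 3.0)

    def test_fixed_point_satisfied_on_random_fit(self):
        expr, bd, _ = simulate_microarray(
            n_genes=200, batch_sizes=(6, 8), seed=3
        )
        design = validate_and_build_design(expr, bd)
        fit = fit_standardization(expr, design)
        pri = estimate_hyperpriors(fit)
        post = parametric_posterior(fit, pri, tol=1e-6)
        for i in range(2):
            cols = design.samples_of(i)
            n = fit.n_obs[:, i]
            g_next = (
                n * pri.tau2[i] * fit.gamma_hat[:, i]
                + post.delta2_star[:, i] * pri.gamma_bar[i]
            ) / (n * pri.tau2[i] + post.delta2_star[:, i])
            sum2 = np.sum(
                (fit.z[:, cols] - g_next[:, None]) ** 2, axis=1
            )
            d_next = (pri.theta[i] + 0.5 * sum2) / (n / 2 + pri.lam[i] - 1)
            np.testing.assert_allclose(
                g_next, post.gamma_star[:, i], rtol=1e-4, atol=1e-8
            )
            np.testing.assert_allclose(
                d_next, post.delta2_star[:, i], rtol=1e-4
            )

    def test_infinite_prior_variance_limit_no_shrinkage(self):
        """tau2 -> inf leaves gamma* = gamma_hat."""
        expr, bd, _ = simulate_microarray(
            n_genes=50, batch_sizes=(5, 5), seed=4
        )
        design = validate_and_build_design(expr, bd)
        fit = fit_standardization(expr, design)
        pri = estimate_hyperpriors(fit)
        pri.tau2 = np.full_like(pri.tau2, 1e12)
        post = parametric_posterior(fit, pri)
        np.testing.assert_allclose(
            post.gamma_star, fit.gamma_hat, rtol=1e-6, atol=1e-9
        )


class TestNonparametricPosterior:
    def test_two_genes_swap_estimates(self):
        """With exactly two retained genes each gene's posterior is the
        other gene's estimate (single-donor leave-one-out)."""
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, size=(2, 8)) + np.repeat([0, 1.0], 4)
        _, fit = _fit(y, ["A"] * 4 + ["B"] * 4)
        post = nonparametric_posterior(fit)
        np.testing.assert_allclose(post.gamma_star[0], fit.gamma_hat[1])
        np.testing.assert_allclose(post.gamma_star[1], fit.gamma_hat[0])
        np.testing.assert_allclose(post.delta2_star[0], fit.delta2_hat[1])

    def test_brute_force_oracle(self):
        """Vectorized posterior equals an independent double-loop
        recomputation of the likelihood-weighted sums."""
        expr, bd, _ = simulate_microarray(
            n_genes=20, batch_sizes=(4, 5), seed=6
        )
        design = validate_and_build_design(expr, bd)
        fit = fit_standardization(expr, design)
        post = nonparametric_posterior(fit)
        G = 20
        for i in range(2):
            cols = design.samples_of(i)
            for g in range(G):
                logw = np.full(G, -np.inf)
                for h in range(G):
                    if h == g:
                        continue
                    s = 0.0
                    for zval in fit.z[g, cols]:
                        s += -0.5 * (
                            (zval - fit.gamma_hat[h, i]) ** 2
                            / fit.delta2_hat[h, i]
                            + np.log(2 * np.pi * fit.delta2_hat[h, i])
                        )
                    logw[h] = s
                w = np.exp(logw - logw.max())
                w /= w.sum()
                assert abs(w @ fit.gamma_hat[:, i] - post.gamma_star[g, i]) < 1e-10
                assert abs(w @ fit.delta2_hat[:, i] - post.delta2_star[g, i]) < 1e-10


class TestAdjustment:
    def test_identity_posterior_roundtrip_exact(self):
        """gamma*=0, delta2*=1 everywhere reproduces the input
        bit-for-bit."""
        rng = np.random.default_rng(7)
        y = rng.normal(8, 2, size=(30, 10))
        em, fit = _fit(y, ["A"] * 5 + ["B"] * 5)
        post = Posterior(
            gamma_star=np.zeros_like(fit.gamma_hat),
            delta2_star=np.ones_like(fit.delta2_hat),
        )
        out = apply_adjustment(fit, post, original=em.values)
        assert np.array_equal(out, em.values)

    def test_batch_means_equalized_on_toy(self):
        """Continuing the standardization example with gamma* =
        gamma_hat: corrected batch means agree per gene."""
        em, fit = _fit([[0, 2, 4, 6], [1, 2, 5, 6]], ["A", "A", "B", "B"])
        post = Posterior(
            gamma_star=fit.gamma_hat.copy(),
            delta2_star=fit.delta2_hat.copy(),
        )
        out = apply_adjustment(fit, post, original=em.values)
        np.testing.assert_allclose(
            out[:, :2].mean(axis=1), out[:, 2:].mean(axis=1)
        )
        assert out[0, :2].mean() == pytest.approx(3.0)


class TestPycombatNorm:
    def test_matches_reference_implementation(self, toy_expression):
        expr, labels, _ = toy_expression
        out = pycombat_norm(expr, labels)
        ref = sva_reference("sva_param.tsv")
        np.testing.assert_allclose(
            out.to_numpy(), ref.to_numpy(), atol=5e-6
        )

    def test_matches_reference_with_covariates(self, toy_expression):
        expr, labels, cov = toy_expression
        out = pycombat_norm(expr, labels, covariates=cov)
        ref = sva_reference("sva_param_cov.tsv")
        np.testing.assert_allclose(
            out.to_numpy(), ref.to_numpy(), atol=1e-5
        )

    def test_matches_reference_nonparametric(self, toy_expression):
        expr, labels, _ = toy_expression
        out = pycombat_norm(expr, labels, method="nonparametric")
        ref = sva_reference("sva_nonparam.tsv")
        np.testing.assert_allclose(
            out.to_numpy(), ref.to_numpy(), atol=1e-12
        )

    def test_matches_reference_mean_only(self, toy_expression):
        expr, labels, _ = toy_expression
        out = pycombat_norm(expr, labels, mean_only=True)
        ref = sva_reference("sva_meanonly.tsv")
        np.testing.assert_allclose(
            out.to_numpy(), ref.to_numpy(), atol=1e-12
        )

    def test_matches_reference_ref_batch(self, toy_expression):
        expr, labels, _ = toy_expression
        out = pycombat_norm(expr, labels, ref_batch="B")
        ref = sva_reference("sva_ref.tsv")
        np.testing.assert_allclose(
            out.to_numpy(), ref.to_numpy(), atol=5e-6
        )

    def test_ref_batch_passthrough_bit_exact(self, toy_expression):
        expr, labels, _ = toy_expression
        out = pycombat_norm(expr, labels, ref_batch="A")
        cols = [s for s, b in zip(expr.columns, labels) if b == "A"]
        assert out[cols].equals(expr[cols])

    def test_single_batch_errors(self):
        df = pd.DataFrame(
            np.ones((3, 4)), columns=["a", "b", "c", "d"]
        )
        with pytest.raises(SingleBatchError):
            pycombat_norm(df, ["A", "A", "A", "A"])

    def test_mean_only_preserves_batch_variances(self):
        """Location-only mode equalizes batch means but leaves each
        batch's variance untouched."""
        rng = np.random.default_rng(8)
        G, n = 60, 50
        shift = rng.normal(0, 2, size=G)
        scale = rng.uniform(0.5, 3.0, size=G)
        y = np.hstack(
            [
                rng.normal(8, 1, size=(G, n)),
                rng.normal(8, 1, size=(G, n)) * scale[:, None]
                + shift[:, None],
            ]
        )
        df = pd.DataFrame(y, columns=[f"s{j}" for j in range(2 * n)])
        labels = ["A"] * n + ["B"] * n
        out = pycombat_norm(df, labels, mean_only=True).to_numpy()
        # batch mean gaps shrink strongly
        gap_before = np.abs(y[:, :n].mean(axis=1) - y[:, n:].mean(axis=1))
        gap_after = np.abs(out[:, :n].mean(axis=1) - out[:, n:].mean(axis=1))
        assert np.median(gap_after) < np.median(gap_before) / 5
        # per-batch variances untouched by a location-only shift
        np.testing.assert_allclose(
            out[:, n:].var(axis=1), y[:, n:].var(axis=1), rtol=1e-9
        )
        np.testing.assert_allclose(
            out[:, :n].var(axis=1), y[:, :n].var(axis=1), rtol=1e-9
        )

    def test_missing_values_stay_missing(self):
        rng = np.random.default_rng(9)
        y = rng.normal(8, 1, size=(20, 8))
        y[3, 2] = np.nan
        df = pd.DataFrame(y, columns=[f"s{j}" for j in range(8)])
        out = pycombat_norm(df, ["A"] * 4 + ["B"] * 4)
        assert np.isnan(out.iat[3, 2])
        assert np.isnan(out.to_numpy()).sum() == 1

    def test_deterministic_given_input_order(self, toy_expression):
        expr, labels, _ = toy_expression
        a = pycombat_norm(expr, labels)
        b = pycombat_norm(expr, labels)
        assert a.equals(b)
        c = pycombat_norm(expr, labels, method="nonparametric")
        d = pycombat_norm(expr, labels, method="nonparametric")
        assert c.equals(d)
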