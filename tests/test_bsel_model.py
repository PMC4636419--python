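"""Likelihood, sampler, DIC and stepwise selection of the BSEL model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from bselsdm.background import LabeledSiteSet
from bselsdm.bsel_model import (
    BSELSpec,
    PosteriorFit,
    bulk_ess,
    compute_dic,
    dic_from_deviance,
    forward_stepwise,
    histogram_mode,
    linear_predictor,
    log_posterior,
    sample_posterior,
    split_rhat,
    summarize_effects,
)


def _manual_sites(X: dict, y: np.ndarray, u=None, v=None, M=1) -> LabeledSiteSet:
    """Assemble a LabeledSiteSet directly from arrays (already standardized)."""
    n = len(y)
    u = np.zeros(n) if u is None else np.asarray(u, dtype=float)
    v = np.zeros(n) if v is None else np.asarray(v, dtype=float)
    labels = np.tile(np.asarray(y), (M, 1))
    kind = np.where(np.asarray(y) == 1, "presence", "background")
    return LabeledSiteSet(
        x=u.copy(), y=v.copy(), site_kind=kind, labels=labels,
        covariates=pd.DataFrame({k: np.asarray(val, dtype=float) for k, val in X.items()}),
        u=u, v=v, p_star=np.full(n, 0.5),
    )


class TestLinearPredictor:
    def test_zero_coefficients_give_half(self, rng):
        spec = BSELSpec(covariates=("a",), expanded=("a",))
        x = rng.normal(size=20)
        eta = linear_predictor(spec, np.zeros(4), {"a": x}, np.zeros(20), np.zeros(20))
        assert np.allclose(expit(eta), 0.5)

    def test_zero_expansion_reduces_to_plain_logistic(self, rng):
        """With expansion slopes 0 the model is ordinary logistic regression."""
        spec = BSELSpec(covariates=("a", "b"), expanded=("a", "b"))
        x = {"a": rng.normal(size=50), "b": rng.normal(size=50)}
        u, v = rng.normal(size=50), rng.normal(size=50)
        theta = np.array([0.3, 1.2, 0.0, 0.0, -0.7, 0.0, 0.0])
        eta = linear_predictor(spec, theta, x, u, v)
        plain = 0.3 + 1.2 * x["a"] - 0.7 * x["b"]
        np.testing.assert_allclose(eta, plain, atol=1e-12)

    def test_positive_du_makes_effect_increase_eastward(self):
        spec = BSELSpec(covariates=("a",), expanded=("a",))
        theta = np.array([0.0, 1.0, 0.5, 0.0])  # d0=1, du=0.5
        x = {"a": np.ones(2)}
        eta = linear_predictor(spec, theta, x, np.array([0.0, 1.0]), np.zeros(2))
        assert eta[1] > eta[0]
        assert eta[1] - eta[0] == pytest.approx(0.5)

    def test_missing_covariate_raises(self):
        spec = BSELSpec(covariates=("missing",))
        with pytest.raises(KeyError):
            linear_predictor(spec, np.zeros(2), {"a": np.ones(3)}, np.zeros(3), np.zeros(3))


class TestLogPosterior:
    def test_single_site_closed_form(self):
        spec = BSELSpec(prior_sd=10.0)
        sites = _manual_sites({}, np.array([1]))
        lp = log_posterior(spec, np.zeros(1), sites)
        expected = np.log(0.5) + norm.logpdf(0.0, 0.0, 10.0)
        assert lp == pytest.approx(expected, abs=1e-12)

    def test_duplicate_path_oracle(self, rng):
        """Differences of log-posteriors match a from-scratch recomputation."""
        spec = BSELSpec(covariates=("a",), expanded=("a",), prior_sd=5.0)
        n = 40
        x = rng.normal(size=n)
        u, v = rng.normal(size=n), rng.normal(size=n)
        y = rng.integers(0, 2, n)
        sites = _manual_sites({"a": x}, y, u, v)
        t1 = rng.normal(size=4)
        t2 = rng.normal(size=4)

        def oracle(theta):
            eta = theta[0] + (theta[1] + theta[2] * u + theta[3] * v) * x
            p = expit(eta)
            ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
            return ll + norm.logpdf(theta, 0, 5.0).sum()

        d_impl = log_posterior(spec, t1, sites) - log_posterior(spec, t2, sites)
        d_orac = oracle(t1) - oracle(t2)
        assert d_impl == pytest.approx(d_orac, abs=1e-10)

    def test_extra_zero_coefficient_adds_only_its_prior(self, rng):
        n = 30
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = rng.integers(0, 2, n)
        s1 = _manual_sites({"a": x}, y)
        s2 = _manual_sites({"a": x, "b": z}, y)
        spec1 = BSELSpec(covariates=("a",), prior_sd=10.0)
        spec2 = BSELSpec(covariates=("a", "b"), prior_sd=10.0)
        theta = np.array([0.4, -1.1])
        lp1 = log_posterior(spec1, theta, s1)
        lp2 = log_posterior(spec2, np.append(theta, 0.0), s2)
        assert lp2 - lp1 == pytest.approx(norm.logpdf(0.0, 0.0, 10.0), abs=1e-12)

    def test_finite_for_extreme_coefficients(self, rng):
        spec = BSELSpec(covariates=("a",), prior_sd=10.0)
        sites = _manual_sites({"a": rng.normal(size=10)}, rng.integers(0, 2, 10))
        assert np.isfinite(log_posterior(spec, np.array([500.0, -500.0]), sites))


class TestSampler:
    def test_intercept_only_matches_quadrature(self):
        """Posterior mean of p vs numeric integration of the exact 1-D posterior."""
        k, n = 7, 20
        y = np.array([1] * k + [0] * (n - k))
        sites = _manual_sites({}, y)
        spec = BSELSpec(prior_sd=100.0)
        fit = sample_posterior(spec, sites, chains=3, iterations=4000, seed=11)
        p_mean_mcmc = expit(fit.pooled()[:, 0]).mean()

        b = np.linspace(-10, 10, 20001)
        log_post = k * np.log(expit(b)) + (n - k) * np.log(expit(-b)) + norm.logpdf(b, 0, 100.0)
        w = np.exp(log_post - log_post.max())
        p_mean_exact = np.sum(expit(b) * w) / np.sum(w)
        assert p_mean_mcmc == pytest.approx(p_mean_exact, abs=0.01)

    def test_identical_seeds_identical_draws(self, tiny_scenario):
        spec = BSELSpec(covariates=("bio1",), expanded=("bio1",))
        a = sample_posterior(spec, tiny_scenario.sites, chains=2, iterations=300, seed=3)
        b = sample_posterior(spec, tiny_scenario.sites, chains=2, iterations=300, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_posterior_mean_matches_ml_oracle(self, rng):
        """Plain-logistic limit: posterior mean vs an IRLS fit, n = 1000."""
        import statsmodels.api as sm

        n = 1000
        X = rng.normal(size=(n, 2))
        eta = -0.3 + 0.9 * X[:, 0] - 0.6 * X[:, 1]
        y = (rng.random(n) < expit(eta)).astype(int)
        sites = _manual_sites({"a": X[:, 0], "b": X[:, 1]}, y)
        spec = BSELSpec(covariates=("a", "b"), prior_sd=10.0)
        fit = sample_posterior(spec, sites, chains=3, iterations=4000, seed=21)
        assert fit.converged
        pooled = fit.pooled()
        glm = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        for j in range(3):
            post_mean = pooled[:, j].mean()
            post_sd = pooled[:, j].std()
            assert abs(post_mean - glm.params[j]) < 3 * post_sd

    def test_diagnostics_match_arviz(self, rng):
        """Own split-rhat / bulk ESS vs the arviz reference implementation."""
        import warnings

        import arviz as az

        x = np.empty((4, 1500, 2))
        for c in range(4):
            z = rng.normal(size=(1500, 2))
            for i in range(1, 1500):
                z[i] = 0.6 * z[i - 1] + np.sqrt(1 - 0.36) * z[i]
            x[c] = z
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_ref = az.rhat(az.convert_to_dataset(x))["x"].to_numpy()
            e_ref = az.ess(az.convert_to_dataset(x))["x"].to_numpy()
        np.testing.assert_allclose(split_rhat(x), r_ref, atol=5e-3)
        np.testing.assert_allclose(bulk_ess(x), e_ref, rtol=0.1)


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self, rng):
        """All draws identical: pD = 0 and DIC = D(theta_bar) exactly."""
        spec = BSELSpec(covariates=("a",), prior_sd=10.0)
        sites = _manual_sites({"a": rng.normal(size=25)}, rng.integers(0, 2, 25))
        theta = np.array([0.2, -0.4])
        from bselsdm.bsel_model import design_matrix, _bernoulli_loglik

        Z = design_matrix(spec, sites.covariates, sites.u, sites.v)
        d0 = -2.0 * float(_bernoulli_loglik(theta[None], Z, sites.labels[0].astype(float))[0])
        samples = np.tile(theta, (2, 1, 50, 1))
        deviance = np.full((2, 1, 50), d0)
        fit = PosteriorFit(
            spec=spec, param_names=spec.param_names, samples=samples,
            deviance=deviance, rhat_max=1.0, ess_min=1e9, converged=True, seed=0,
        )
        dic, dbar, pd_ = compute_dic(fit, sites)
        assert pd_ == pytest.approx(0.0, abs=1e-10)
        assert dic == pytest.approx(d0, abs=1e-10)
        assert dic == pytest.approx(dbar + pd_)

    def test_normal_mean_toy_matches_conjugate_closed_form(self, rng):
        """DIC machinery vs the analytic result for a normal mean with known sigma."""
        n, sigma, tau0 = 30, 2.0, 10.0
        y = rng.normal(1.0, sigma, n)
        var_n = 1.0 / (n / sigma**2 + 1.0 / tau0**2)
        mean_n = var_n * y.sum() / sigma**2

        S = 200_000
        mu = rng.normal(mean_n, np.sqrt(var_n), S)
        const = n * np.log(2 * np.pi * sigma**2)
        dev = const + ((y[None, :] - mu[:, None]) ** 2).sum(axis=1) / sigma**2
        dev_at_mean = const + ((y - mean_n) ** 2).sum() / sigma**2
        dic, dbar, pd_ = dic_from_deviance(dev, dev_at_mean)

        pd_exact = n * var_n / sigma**2
        dbar_exact = dev_at_mean + pd_exact
        assert pd_ == pytest.approx(pd_exact, abs=0.02)
        assert dic == pytest.approx(dbar_exact + pd_exact, abs=0.05)

    def test_noise_covariate_increases_pd_within_range(self, tiny_scenario):
        """An inert expanded covariate adds between 0 and ~3 effective parameters."""
        sites = tiny_scenario.sites
        null = sample_posterior(BSELSpec(), sites, chains=2, iterations=2500, seed=31)
        noise = sample_posterior(
            BSELSpec(covariates=("bio3",), expanded=("bio3",)),
            sites, chains=2, iterations=2500, seed=32,
        )
        _, _, pd_null = compute_dic(null, sites, force=True)
        _, _, pd_noise = compute_dic(noise, sites, force=True)
        assert 0.0 < pd_noise - pd_null < 4.0

    def test_unconverged_fit_refused(self, rng):
        spec = BSELSpec()
        sites = _manual_sites({}, np.array([1, 0]))
        fit = PosteriorFit(
            spec=spec, param_names=spec.param_names,
            samples=np.zeros((2, 1, 10, 1)), deviance=np.zeros((2, 1, 10)),
            rhat_max=2.0, ess_min=5.0, converged=False, seed=0,
        )
        from bselsdm.bsel_model import UnconvergedFit

        with pytest.raises(UnconvergedFit):
            compute_dic(fit, sites)


class TestSummaries:
    def test_histogram_mode_lower_bin_tie_break(self):
        s = np.concatenate([np.full(10, 0.0), np.full(10, 1.0)])
        # bins of equal count: the first (lower) maximal bin wins
        assert histogram_mode(s) < 0.5

    def test_mode_near_mean_for_symmetric_sample(self, rng):
        s = rng.normal(2.0, 1.0, 200_000)
        bin_width = (s.max() - s.min()) / 100
        assert abs(histogram_mode(s) - s.mean()) < 2 * bin_width

    def test_ci_equals_sorting_oracle(self, rng):
        spec = BSELSpec(covariates=("a",), prior_sd=10.0)
        samples = rng.normal(size=(2, 1, 500, 2))
        fit = PosteriorFit(
            spec=spec, param_names=spec.param_names, samples=samples,
            deviance=np.zeros((2, 1, 500)), rhat_max=1.0, ess_min=1e9,
            converged=True, seed=0,
        )
        eff = summarize_effects(fit)[0]
        pooled = np.sort(samples[..., 1].ravel())
        lo = np.quantile(pooled, 0.025)
        hi = np.quantile(pooled, 0.975)
        assert eff.ci_lower == pytest.approx(lo)
        assert eff.ci_upper == pytest.approx(hi)
        assert eff.ci_lower <= eff.ci_upper


class TestStepwise:
    def test_true_driver_selected_and_dic_drops(self, tiny_scenario):
        res = forward_stepwise(
            tiny_scenario.sites.covariate_names(), tiny_scenario.sites,
            chains=2, iterations=2500, seed=41,
        )
        assert "bio1" in res.spec.covariates
        assert res.trace[0]["variable"] == "bio1"
        assert res.trace[0]["dic"] < res.null_dic

    def test_trace_dic_non_increasing(self, tiny_scenario):
        res = forward_stepwise(
            tiny_scenario.sites.covariate_names(), tiny_scenario.sites,
            chains=2, iterations=2500, seed=43,
        )
        dics = [res.null_dic] + [t["dic"] for t in res.trace]
        assert all(a > b for a, b in zip(dics, dics[1:]))

    def test_pure_noise_candidates_rejected(self, rng):
        """Labels independent of covariates: selection mostly stops at null."""
        n = 300
        stopped_at_null = 0
        for s in range(5):
            local = np.random.default_rng(s)
            X = {f"c{j}": local.normal(size=n) for j in range(2)}
            y = (local.random(n) < 0.4).astype(int)
            sites = _manual_sites(X, y)
            res = forward_stepwise(
                list(X), sites, chains=2, iterations=1500, seed=100 + s
            )
            stopped_at_null += len(res.spec.covariates) == 0
        assert stopped_at_null >= 3


class TestImputationPooling:
    def test_pooled_variance_not_below_fixed_label_variance(self, tiny_scenario):
        """Propagating label uncertainty cannot shrink the posterior."""
        sites = tiny_scenario.sites
        spec = BSELSpec(covariates=("bio1",), expanded=("bio1",))
        fit_m = sample_posterior(spec, sites, chains=2, iterations=2500, seed=51)
        # fixed fractional labels at the prior mean: a single deterministic fit
        fixed = LabeledSiteSet(
            x=sites.x, y=sites.y, site_kind=sites.site_kind,
            labels=np.where(sites.is_presence, 1.0, sites.p_star)[None, :],
            covariates=sites.covariates, u=sites.u, v=sites.v,
            p_star=sites.p_star, standardization=sites.standardization,
        )
        fit_f = sample_posterior(spec, fixed, chains=2, iterations=2500, seed=52)
        idx = spec.param_names.index("bio1:d0")
        var_pooled = fit_m.pooled()[:, idx].var()
        var_fixed = fit_f.pooled()[:, idx].var()
        assert var_pooled >= 0.9 * var_fixed
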