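"""Bayesian spatially expanded logistic (BSEL) occurrence model.

The observation at site *i* is Bernoulli with occurrence probability
``p_i = logistic(eta_i)``.  Under the expansion method the effect of each
environmental covariate is allowed to drift linearly across geographic
space: with standardized covariates ``x_k`` and standardized easting /
northing ``(u, v)``,

    eta = beta0 + sum_k (delta_k0 + delta_k1 * u + delta_k2 * v) * x_k .

A covariate therefore contributes one base effect and, when expanded, two
slopes describing how that effect changes across the study area.  All
coefficients get independent Normal(0, prior_sd) priors (default sd 10 on
the standardized scale: weakly informative, proper).

Pseudo-absence label uncertainty enters through multiple imputation: the
model is fitted once per imputed label vector and the posteriors pooled as
an equal-weight mixture (see :mod:`bselsdm.background`).

Posterior sampling uses an adaptive random-walk Metropolis sampler with a
per-walker diagonal proposal whose scales are tuned during burn-in
(Robbins-Monro on the global step size, running variance per coordinate)
and frozen afterwards, so the kept draws come from a valid Markov chain.
Any sampler is conforming if it passes the convergence gate
(max rhat < 1.05, min bulk ESS > 200); diagnostics come from arviz.

Model comparison uses the deviance information criterion,
DIC = Dbar + pD with pD = Dbar - D(theta_bar), computed per imputation and
averaged; forward stepwise selection adds the candidate with the lowest
DIC until no addition improves it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .background import LabeledSiteSet


class UnconvergedFit(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model specification and design matrix


@dataclass(frozen=True)
class BSELSpec:
    """Covariates in the model and whether each carries a spatial expansion."""

    covariates: tuple[str, ...] = ()
    expanded: tuple[str, ...] = ()
    prior_sd: float = 10.0

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates in spec")
        unknown = set(self.expanded) - set(self.covariates)
        if unknown:
            raise ValueError(f"expanded covariates not in model: {sorted(unknown)}")

    @property
    def param_names(self) -> list[str]:
        names = ["beta0"]
        for c in self.covariates:
            names.append(f"{c}:d0")
            if c in self.expanded:
                names.extend([f"{c}:du", f"{c}:dv"])
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def with_covariate(self, name: str, expand: bool = True) -> "BSELSpec":
        return BSELSpec(
            covariates=self.covariates + (name,),
            expanded=self.expanded + ((name,) if expand else ()),
            prior_sd=self.prior_sd,
        )


def design_matrix(
    spec: BSELSpec, covariates, u: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Columns: intercept, then per covariate x_k (and u*x_k, v*x_k if expanded)."""
    n = u.size
    cols = [np.ones(n)]
    for c in spec.covariates:
        if hasattr(covariates, "columns"):
            if c not in covariates.columns:
                raise KeyError(f"missing covariate {c!r}")
            x = covariates[c].to_numpy(dtype=float)
        else:
            x = np.asarray(covariates[c], dtype=float)
        cols.append(x)
        if c in spec.expanded:
            cols.append(u * x)
            cols.append(v * x)
    return np.column_stack(cols)


def linear_predictor(
    spec: BSELSpec, theta: np.ndarray, covariates, u, v
) -> np.ndarray:
    """eta for coefficient vector(s) theta; accepts (P,) or (W, P) theta."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    Z = design_matrix(spec, covariates, u, v)
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        if theta.size != Z.shape[1]:
            raise ValueError("coefficient vector length does not match the model")
        return Z @ theta
    return theta @ Z.T


def occurrence_probability(spec, theta, covariates, u, v) -> np.ndarray:
    from scipy.special import expit

    return expit(linear_predictor(spec, theta, covariates, u, v))


# ---------------------------------------------------------------------------
# posterior density


def _bernoulli_loglik(theta: np.ndarray, Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sum_i [y eta - log(1 + e^eta)]; theta (W,P), y (W,n) or (n,) -> (W,)."""
    eta = theta @ Z.T
    return np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)


def log_posterior(
    spec: BSELSpec, theta: np.ndarray, sites: LabeledSiteSet, imputation: int = 0
) -> float:
    """Bernoulli log-likelihood of imputation ``imputation`` plus the prior.

    Computed on the log-odds scale (no explicit p in [0, 1] is formed), so
    the value is finite for every finite coefficient vector.
    """
    Z = design_matrix(spec, sites.covariates, sites.u, sites.v)
    theta = np.asarray(theta, dtype=float)
    y = sites.labels[imputation].astype(float)
    ll = float(_bernoulli_loglik(theta[None, :], Z, y)[0])
    sd = spec.prior_sd
    lp = -0.5 * np.sum(theta**2) / sd**2 - theta.size * (
        np.log(sd) + 0.5 * np.log(2.0 * np.pi)
    )
    return ll + float(lp)


# ---------------------------------------------------------------------------
# posterior fit container


@dataclass
class PosteriorFit:
    """Posterior draws per chain and imputation, with diagnostics.

    ``samples`` has shape (chains, M, draws, P); ``deviance`` has shape
    (chains, M, draws) where the deviance of a draw is evaluated against
    its own imputation's labels.
    """

    spec: BSELSpec
    param_names: list[str]
    samples: np.ndarray
    deviance: np.ndarray
    rhat_max: float
    ess_min: float
    converged: bool
    seed: int | None
    settings: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_imputations(self) -> int:
        return self.samples.shape[1]

    def pooled(self) -> np.ndarray:
        """All draws pooled across chains and imputations: (N, P)."""
        return self.samples.reshape(-1, self.samples.shape[-1])

    def posterior_mean(self) -> np.ndarray:
        return self.pooled().mean(axis=0)


def _split(chains_draws: np.ndarray) -> np.ndarray:
    """Halve each chain: (C, N, ...) -> (2C, N//2, ...)."""
    n = chains_draws.shape[1] // 2
    return np.concatenate([chains_draws[:, :n], chains_draws[:, n : 2 * n]], axis=0)


def split_rhat(chains_draws: np.ndarray) -> np.ndarray:
    """Classic split-chain potential scale reduction factor, per parameter.

    Input shape (chains, draws, P); chains are split in half first, so
    within-chain drift also inflates the statistic.
    """
    x = _split(np.asarray(chains_draws, dtype=float))
    c, n, _ = x.shape
    chain_mean = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean(axis=0)
    b = n * chain_mean.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return np.sqrt(var_hat / np.maximum(w, 1e-300))


def bulk_ess(chains_draws: np.ndarray) -> np.ndarray:
    """Effective sample size per parameter (Geyer initial-monotone, split chains)."""
    x = _split(np.asarray(chains_draws, dtype=float))
    c, n, P = x.shape
    out = np.empty(P)
    for p in range(P):
        xp = x[:, :, p]
        chain_var = xp.var(axis=1, ddof=1)
        w = chain_var.mean()
        b = n * xp.mean(axis=1).var(ddof=1) if c > 1 else 0.0
        var_hat = (n - 1) / n * w + b / n
        if var_hat <= 0:
            out[p] = c * n
            continue
        centered = xp - xp.mean(axis=1, keepdims=True)
        nfft = 1 << int(np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(centered, nfft, axis=1)
        acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
        rho = 1.0 - (w - acov.mean(axis=0)) / var_hat  # combined-chain autocorr
        # Geyer: pair sums P_k = rho_2k + rho_2k+1, truncate at the first
        # negative pair, enforce monotone non-increase; tau = 2*sum(P) - rho_0
        n_pairs = len(rho) // 2
        pair = rho[0 : 2 * n_pairs : 2] + rho[1 : 2 * n_pairs : 2]
        total = 0.0
        running_min = np.inf
        for t in range(n_pairs):
            if pair[t] < 0:
                break
            running_min = min(running_min, pair[t])
            total += running_min
        tau = 2.0 * total - rho[0]
        out[p] = c * n / max(tau, 1e-12)
    return out


def _diagnostics(samples: np.ndarray) -> tuple[float, float]:
    """Worst-case split-rhat and bulk ESS across parameters and imputations."""
    chains, M, draws, P = samples.shape
    rhat_max = 0.0
    ess_min = np.inf
    for m in range(M):
        arr = samples[:, m]  # (chains, draws, P)
        rhat_max = max(rhat_max, float(np.nanmax(split_rhat(arr))))
        ess_min = min(ess_min, float(np.nanmin(bulk_ess(arr))))
    return rhat_max, ess_min


def sample_posterior(
    spec: BSELSpec,
    sites: LabeledSiteSet,
    chains: int = 3,
    iterations: int = 6000,
    burn: int | None = None,
    seed: int | None = None,
    check_convergence: bool = True,
) -> PosteriorFit:
    """Adaptive random-walk Metropolis draws from the BSEL posterior.

    One independent chain set per imputation (all walkers advance in a
    single vectorized loop).  ``iterations`` counts post-burn-in draws per
    chain; ``burn`` defaults to ``iterations // 2``.  Fully deterministic
    given ``seed``.
    """
    y_any = sites.labels
    if not (sites.is_presence.any() and (~sites.is_presence).any()):
        raise ValueError("need at least one presence and one background site")
    if burn is None:
        burn = max(iterations // 2, 500)
    Z = design_matrix(spec, sites.covariates, sites.u, sites.v)
    n, P = Z.shape
    M = sites.n_imputations
    W = chains * M  # walkers, laid out as (chains, M)
    Y = np.repeat(y_any[None, :, :].astype(float), chains, axis=0).reshape(W, n)

    rng = np.random.default_rng(seed)
    prior_var = spec.prior_sd**2

    def logpost(th: np.ndarray) -> np.ndarray:
        ll = _bernoulli_loglik(th, Z, Y)
        lp = -0.5 * np.sum(th**2, axis=1) / prior_var
        return ll + lp

    # Laplace preconditioning: Newton MAP per imputation gives the proposal
    # shape (posterior covariance approximation) and the chain start points;
    # only the global step size is tuned during burn-in, so post-burn draws
    # come from a fixed-kernel Metropolis chain.
    from scipy.special import expit

    chol_m = np.empty((M, P, P))
    map_m = np.empty((M, P))
    for m in range(M):
        ym = y_any[m].astype(float)
        beta = np.zeros(P)
        for _ in range(50):
            p = expit(Z @ beta)
            g = Z.T @ (ym - p) - beta / prior_var
            H = (Z * (p * (1 - p))[:, None]).T @ Z + np.eye(P) / prior_var
            step_vec = np.linalg.solve(H, g)
            beta = beta + step_vec
            if np.max(np.abs(step_vec)) < 1e-10:
                break
        map_m[m] = beta
        chol_m[m] = np.linalg.cholesky(np.linalg.inv(H))
    # walkers laid out as (chains, M)
    chol = np.tile(chol_m, (chains, 1, 1, 1)).reshape(W, P, P)
    theta = np.tile(map_m, (chains, 1)).reshape(W, P)
    theta = theta + 0.5 * np.einsum("wij,wj->wi", chol, rng.normal(size=(W, P)))

    lp_cur = logpost(theta)
    if not np.all(np.isfinite(lp_cur)):
        raise RuntimeError("non-finite log-posterior at initialization")

    log_scale = np.full(W, np.log(2.38 / np.sqrt(P)))
    target_accept = 0.234

    draws = np.empty((W, iterations, P))
    dev = np.empty((W, iterations))

    for it in range(burn + iterations):
        z = rng.normal(size=(W, P))
        prop = theta + np.exp(log_scale)[:, None] * np.einsum("wij,wj->wi", chol, z)
        lp_prop = logpost(prop)
        accept = np.log(rng.random(W)) < (lp_prop - lp_cur)
        theta[accept] = prop[accept]
        lp_cur[accept] = lp_prop[accept]
        if it < burn:
            log_scale += (it + 1) ** (-0.6) * (accept.astype(float) - target_accept)
        else:
            k = it - burn
            draws[:, k] = theta
            dev[:, k] = -2.0 * _bernoulli_loglik(theta, Z, Y)

    samples = draws.reshape(chains, M, iterations, P)
    deviance = dev.reshape(chains, M, iterations)
    rhat_max, ess_min = _diagnostics(samples)
    converged = bool(rhat_max < 1.05 and ess_min > 200)
    if check_convergence and not converged:
        warnings.warn(
            f"fit flagged unconverged: rhat={rhat_max:.3f}, ess={ess_min:.0f}",
            stacklevel=2,
        )
    return PosteriorFit(
        spec=spec,
        param_names=spec.param_names,
        samples=samples,
        deviance=deviance,
        rhat_max=rhat_max,
        ess_min=ess_min,
        converged=converged,
        seed=seed,
        settings={"chains": chains, "iterations": iterations, "burn": burn},
    )


# ---------------------------------------------------------------------------
# DIC


def dic_from_deviance(deviance_draws: np.ndarray, deviance_at_mean: float) -> tuple[float, float, float]:
    """(DIC, Dbar, pD) from a deviance trace and D at the posterior mean."""
    dbar = float(np.mean(deviance_draws))
    pd_ = dbar - float(deviance_at_mean)
    return dbar + pd_, dbar, pd_


def compute_dic(
    fit: PosteriorFit, sites: LabeledSiteSet, force: bool = False
) -> tuple[float, float, float]:
    """DIC = Dbar + pD, pD = Dbar - D(theta_bar), averaged over imputations.

    Within each imputation the deviance uses that imputation's labels and
    theta_bar is that imputation's posterior mean; the reported numbers are
    the equal-weight averages, so the identity DIC = Dbar + pD holds
    exactly as stored.
    """
    if not fit.converged and not force:
        raise UnconvergedFit(
            f"refusing DIC on unconverged fit (rhat={fit.rhat_max:.3f}, "
            f"ess={fit.ess_min:.0f}); pass force=True to override"
        )
    Z = design_matrix(fit.spec, sites.covariates, sites.u, sites.v)
    M = fit.n_imputations
    dbars = np.empty(M)
    dhats = np.empty(M)
    for m in range(M):
        y = sites.labels[m].astype(float)
        dbars[m] = fit.deviance[:, m].mean()
        theta_bar = fit.samples[:, m].reshape(-1, Z.shape[1]).mean(axis=0)
        dhats[m] = -2.0 * float(_bernoulli_loglik(theta_bar[None, :], Z, y)[0])
    dbar = float(dbars.mean())
    pd_ = dbar - float(dhats.mean())
    if pd_ < 0:
        warnings.warn(f"negative pD ({pd_:.2f}); posterior may be multimodal", stacklevel=2)
    return dbar + pd_, dbar, pd_


# ---------------------------------------------------------------------------
# effect summaries


def histogram_mode(samples: np.ndarray, bins: int = 100) -> float:
    """Mode as the centre of the fullest of 100 equal bins (lower bin on ties)."""
    samples = np.asarray(samples, dtype=float)
    lo, hi = samples.min(), samples.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(samples, bins=bins, range=(lo, hi))
    k = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    return float(0.5 * (edges[k] + edges[k + 1]))


@dataclass
class ExpandedCoefficient:
    """Posterior summary of one covariate's study-area mean effect."""

    name: str
    mode: float
    ci_lower: float
    ci_upper: float
    delta0_mean: float
    delta_u_mean: float
    delta_v_mean: float


def summarize_effects(
    fit: PosteriorFit,
    spec: BSELSpec | None = None,
    mean_u: float = 0.0,
    mean_v: float = 0.0,
) -> list[ExpandedCoefficient]:
    """Per covariate: mode and equal-tailed 95% CI of the study-area mean effect.

    The study-area mean effect per draw is
    ``delta_bar = d0 + du * mean(u) + dv * mean(v)`` with the means taken
    over grid cells; with grid-standardized coordinates those means are 0
    and delta_bar reduces to d0.  A warning is raised if the histogram mode
    falls outside the CI (possible under multimodality); both are still
    reported.
    """
    if spec is None:
        spec = fit.spec
    pooled = fit.pooled()
    names = fit.param_names
    out = []
    for c in spec.covariates:
        d0 = pooled[:, names.index(f"{c}:d0")]
        du = pooled[:, names.index(f"{c}:du")] if f"{c}:du" in names else np.zeros_like(d0)
        dv = pooled[:, names.index(f"{c}:dv")] if f"{c}:dv" in names else np.zeros_like(d0)
        delta_bar = d0 + du * mean_u + dv * mean_v
        lo, hi = np.quantile(delta_bar, [0.025, 0.975])
        mode = histogram_mode(delta_bar)
        if not (lo <= mode <= hi):
            warnings.warn(
                f"{c}: histogram mode {mode:.3f} outside 95% CI [{lo:.3f}, {hi:.3f}]",
                stacklevel=2,
            )
        out.append(
            ExpandedCoefficient(
                name=c,
                mode=mode,
                ci_lower=float(lo),
                ci_upper=float(hi),
                delta0_mean=float(d0.mean()),
                delta_u_mean=float(du.mean()),
                delta_v_mean=float(dv.mean()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# forward stepwise selection by DIC


@dataclass
class StepwiseResult:
    spec: BSELSpec
    fit: PosteriorFit
    trace: list[dict]
    null_dic: float


def forward_stepwise(
    candidates: Sequence[str],
    sites: LabeledSiteSet,
    chains: int = 3,
    iterations: int = 4000,
    seed: int | None = None,
    prior_sd: float = 10.0,
    expand: bool = True,
    require_convergence: bool = True,
) -> StepwiseResult:
    """Forward stepwise variable selection on DIC.

    Starts from the intercept-only null model; each round fits every
    remaining candidate added to the current model (with spatial expansion
    when ``expand``) and accepts the one with the lowest DIC; stops when no
    addition lowers DIC.  The trace records the DIC after each accepted
    addition, in acceptance order.
    """
    if not candidates:
        raise ValueError("no candidate covariates")
    ss = np.random.SeedSequence(seed)

    def _fit(spec: BSELSpec, child_seed) -> tuple[PosteriorFit, float]:
        seed_val = int(child_seed.generate_state(1)[0] % (2**31))
        fit = sample_posterior(
            spec, sites, chains=chains, iterations=iterations,
            seed=seed_val, check_convergence=False,
        )
        if not fit.converged:
            # one retry with a longer chain before declaring the fit unusable
            fit = sample_posterior(
                spec, sites, chains=chains, iterations=3 * iterations,
                seed=seed_val + 1, check_convergence=False,
            )
        dic, _, _ = compute_dic(fit, sites, force=True)
        return fit, dic

    null_spec = BSELSpec(prior_sd=prior_sd)
    children = iter(ss.spawn(1 + (len(candidates) * (len(candidates) + 1)) // 2 + len(candidates)))
    current_fit, current_dic = _fit(null_spec, next(children))
    if require_convergence and not current_fit.converged:
        raise UnconvergedFit("null model failed to converge")
    current_spec = null_spec
    trace: list[dict] = []
    null_dic = current_dic
    remaining = list(candidates)

    while remaining:
        results = []
        any_converged = False
        for c in remaining:
            spec_c = current_spec.with_covariate(c, expand=expand)
            fit_c, dic_c = _fit(spec_c, next(children))
            any_converged |= fit_c.converged
            results.append((dic_c, c, spec_c, fit_c))
        if require_convergence and not any_converged:
            raise UnconvergedFit("all candidate fits unconverged in a stepwise round")
        dic_best, c_best, spec_best, fit_best = min(results, key=lambda t: t[0])
        if dic_best >= current_dic:
            break
        current_spec, current_fit, current_dic = spec_best, fit_best, dic_best
        remaining.remove(c_best)
        effects = summarize_effects(current_fit)
        eff = next(e for e in effects if e.name == c_best)
        trace.append(
            {
                "variable": c_best,
                "dic": current_dic,
                "delta_mode": eff.mode,
                "delta_ci": [eff.ci_lower, eff.ci_upper],
            }
        )
    return StepwiseResult(spec=current_spec, fit=current_fit, trace=trace, null_dic=null_dic)
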