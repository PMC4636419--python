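# Methods

`bselsdm` implements a Bayesian spatially expanded logistic (BSEL) species
distribution analysis for presence-only occurrence data, exercised end to
end on synthetic study systems with known parameters. This note records the
model, the design choices made where the published method leaves the design
open, the defaults and their rationale, and the limitations the test suite
does and does not speak to.

## Coordinate framework

All analysis happens in projected kilometres under a spherical Lambert
azimuthal equal-area projection centred on the Gran Chaco / Monte region
(lon −64°, lat −32°, authalic radius 6371.0088 km). An equal-area frame is
required for two quantities to be meaningful: point densities per km²
(background-site placement) and kernel bandwidths in km. Within a region
~3000 km across, planar distances in this projection agree with
great-circle distances to well under 1% (asserted against a haversine
oracle in the tests). Rasters are regular north-up grids, cell-centre
registered, 5 km cells by default; covariates are sampled at points by
nearest-cell lookup — bilinear interpolation would invent sub-cell
structure the 5-km analysis resolution does not support. Any point falling
on a nodata cell of any band is dropped with a warning.

Raster I/O uses single-band float32 TIFF files with a JSON sidecar carrying
the grid origin, cell size, CRS identifier and nodata value. The
write→read round trip is bit-exact for finite float32 cells. Loading a
stack of layers requires identical grid geometry; mismatches are an error,
never silently resampled.

## Occurrence curation

Raw records (lon, lat, date, source) pass through four flagging stages:
date window (default 1950–2012, inclusive), named exclusion polygons
(boundary counts as inside), study-area clip, and 5-km de-duplication. No
record is deleted — every input row carries a flag and a reason, so the
audit CSV reconstructs the input exactly.

De-duplication keeps only the latest observation among records closer than
the radius. The published rule does not specify how chains of overlapping
points resolve, nor the tie-break for equal dates; we use a greedy pass in
date-descending order (stable, ties broken by input order, first wins): a
record survives iff no already-accepted record lies within the radius.
This is deterministic, idempotent, and guarantees the kept set's minimum
pairwise distance exceeds the radius (asserted on every run). Distances
are planar projected km; at a 5-km radius the planar/geodesic difference
is negligible. Year-only dates are read as January 1 of that year —
permissive parsing appropriate to museum data; unparseable dates are
flagged, never silently dropped.

## Prior observation surface

The prior probability of an observation at cell *i*, p\*ᵢ, comes from a
kernel density estimate of the curated presences with the quartic
(biweight) kernel K_h(d) = 3/(πh²)·(1 − d²/h²)² for d ≤ h — the 2-D kernel
behind the point-pattern software the original analysis used. Each
point's kernel integrates to 1, so the surface integral is ≈ n up to
boundary truncation; no edge correction is applied (the normalisation
below absorbs the overall scale).

The density-to-probability mapping is not stated in the published
analysis; we use the simplest monotone map onto (0, 1): divide by the
surface maximum and clamp to [ε, 1 − ε] with ε = 10⁻³ (configurable).
The clamp keeps every Bernoulli(p\*) likelihood term proper. Cell ranking
is preserved exactly.

The bandwidth is likewise unreported. The default is the normal-reference
rule h = 1.06·σ̂·n^(−1/5) with σ̂ the mean of the two axis-wise sample
standard deviations (km); the value used is recorded in run metadata and
can be overridden. This is a reproducible, scale-equivariant default, not
a claim about the original choice.

## Background sites and label uncertainty

Non-visited (background) sites are placed uniformly at random inside the
study area by rejection sampling, N = round(density × area). The default
density, 0.0004/km², is the observed-record density of the motivating
study; the generator's flagship scenario applies the underlying rule —
background density matched to the realised presence density — rather than
the literal constant, since the constant is that rule's value for a much
larger study area.

Because background sites carry no real observation, their 0/1 labels are
*imputed*: M independent label vectors are drawn with
labelᵢₘ ~ Bernoulli(p\*ᵢ), the model is fitted once per imputation, and
the posteriors are pooled as an equal-weight mixture. M = 10 by default.
This multiple-imputation reading propagates pseudo-absence uncertainty
into the parameter estimates; a single-model alternative (a per-site
mixture likelihood) would keep one posterior but change the estimand, and
is noted here as the road not taken. Presence sites have label 1 in every
imputation.

Covariates are standardized to z-scores using statistics over the study
grid's cells (not the sites), so effect sizes are comparable across
variables and the expansion coordinates below are centred; constants are
recorded alongside the fit. Zero-variance bands are excluded from the
candidate set with a warning.

## The BSEL model

With standardized covariates x_k and standardized easting/northing (u, v),

    Obs_i ~ Bernoulli(p_i),
    logit p_i = β₀ + Σ_k (δ_k0 + δ_k1·u_i + δ_k2·v_i) · x_k,i .

The first-order expansion in (u, v) is the minimal form consistent with a
coefficient that "varies among locations"; higher orders would add 2+
parameters per covariate without support at these sample sizes. All
coefficients get independent Normal(0, 10) priors on the standardized
scale — weakly informative and proper; the sd is configurable.

The likelihood is evaluated on the log-odds scale
(y·η − log(1 + e^η)), finite for every finite coefficient vector, so no
probability clamping is needed in practice (the documented p ∈
[10⁻¹², 1 − 10⁻¹²] guard is implied by this form).

### Posterior sampling

Sampling uses random-walk Metropolis preconditioned by a Laplace
approximation: per imputation, a Newton/IRLS pass finds the posterior mode
and Hessian; chains start near the mode and propose with the Hessian's
inverse Cholesky factor as the step shape. Only the global step size is
adapted during burn-in (Robbins–Monro toward 0.234 acceptance) and frozen
afterwards, so retained draws come from a fixed-kernel Markov chain. All
chains and imputations advance in one vectorized loop. Defaults: 3 chains
per imputation, burn-in = half the retained length, fully seeded and
bitwise reproducible.

Convergence is gated on max split-R̂ < 1.05 and min bulk ESS > 200 across
parameters and imputations, computed by in-package implementations of the
split-chain potential scale reduction factor and Geyer initial-monotone
ESS (cross-checked against the arviz reference implementations in the
tests). Any sampler passing this gate is conforming; this one is simply
fast and dependency-light for log-concave logistic posteriors.

### DIC and stepwise selection

Deviance is −2 × log-likelihood (prior excluded). Within each imputation,
D̄ₘ is the mean deviance over draws and pDₘ = D̄ₘ − D(θ̄ₘ) with θ̄ₘ that
imputation's posterior mean; reported D̄, pD, DIC are the equal-weight
averages, so DIC = D̄ + pD holds exactly as stored. pD < 0 triggers a
warning (possible under multimodality), not an error.

Forward stepwise selection starts from the intercept-only null; each round
fits every remaining candidate added with its expansion and accepts the
lowest-DIC one; it stops when no addition lowers DIC (no ΔDIC > 2
heuristic — the simplest rule consistent with a monotone selection table).
Previously accepted variables are refitted in every candidate model
(cumulative models). A candidate fit failing the convergence gate is
retried once with a 3× longer chain; a round in which every candidate
still fails aborts the selection.

The per-variable summary δ̄ is the study-area mean effect
δ_k0 + δ_k1·mean(u) + δ_k2·mean(v), with means over grid cells — under
grid standardization those means are 0 and δ̄ reduces to δ_k0. Reported
per covariate: posterior mode (100-bin histogram over the pooled sample
range, lower bin on ties) and equal-tailed 95% CI. If multimodality puts
the mode outside the CI, both are still reported with a warning.

## Prediction and evaluation

Predictions push the pooled posterior (thinned evenly to ≤ 2000 draws,
seeded offset) through the linear predictor at every non-nodata cell,
yielding bands: p_mode (100-bin histogram mode), p_median, p_lo025,
p_hi975, and ci_length = p_hi975 − p_lo025, the per-cell uncertainty
measure on [0, 1] (0 precise, 1 imprecise).

AUC against a continuous prior surface is not operationally defined
(AUC needs binary labels), so two readings are computed and both labelled
as reconstructions: (i) presence-vs-background discrimination of the
median map at the model's own sites; (ii) a prior contrast — K = 100
label draws per cell from Bernoulli(p\*), AUC of the median map against
each, reported as mean ± sd with the effective K (single-class draws
skipped and logged). AUC itself is the Mann–Whitney statistic with the
standard ½ tie credit, verified against O(n²) pair counting.

Threshold reports give, for t ∈ {0.4, 0.5, 0.6}, cell counts and the
mean/max/fraction-above-0.5 of ci_length on each side of t. Protected-area
validation summarises each area by the maximum cell p_median over cells
whose centres fall inside its polygon (an area contains suitable habitat
if any cell does; the mean is also emitted); reported-present areas below
t are omissions, unreported areas at or above t commissions. Areas outside
the grid are flagged and excluded from counts.

## Synthetic study systems

The generator produces everything the pipeline consumes, with known truth:

- **Covariates**: white noise convolved with a Gaussian kernel
  (correlation length 50 km by default, wrap-around boundaries), z-scored
  per band; bands mutually independent. Real bioclimatic layers are
  strongly cross-correlated; independence here is a deliberate
  simplification — tests on these fields say nothing about collinearity
  behaviour.
- **Virtual species**: occupancy p(s) computed through the *same*
  linear-predictor code the fitter uses, so generator/fitter drift is
  structurally impossible. Default truth: β₀ = −0.5; one active covariate
  with (δ₀, δᵤ, δᵥ) = (1.6, 0.5, −0.3); two inert covariates. Chosen for
  moderate prevalence (~0.45), a strong but plausible climatic effect, and
  expansion slopes ~30% of the base effect.
- **Presence-only records**: cells drawn without replacement with
  intensity ∝ p × effort (Gumbel top-k), one record per cell with sub-cell
  jitter and random dates in the study window. Uniform effort reproduces
  the equal-sampling-intensity assumption behind the prior surface;
  spatially varying effort emulates observer bias.
- **Protected areas**: random squares (8–25 km) whose reported presence is
  a Bernoulli draw from the maximum true occupancy inside — known ground
  truth for omission/commission checks.

The flagship scenario is a 60×60 grid of 5-km cells, 3 covariates, 244
presences (the motivating study's record count), matched-density
background (~244 sites), M = 10. Everything regenerates bitwise from one
seed.

## Known limitations

- **Effect attenuation under label imputation.** Background labels come
  from the KDE prior, which is a smoothed, max-normalised estimate of the
  occurrence surface. Fitted effects therefore track the relationship
  implied by p\*, which is systematically weaker than the
  occupancy-generating coefficient; in the flagship scenario the pooled CI
  for δ̄ sits below the generating value. The control experiment in the
  test suite (labels drawn from the true occupancy instead of p\*)
  restores nominal coverage, isolating the attenuation to the
  prior-imputation device itself. Variable *selection* is robust to this;
  effect *magnitudes* from this class of model should be read as
  observation-surface effects, not occupancy effects.
- The multiple-imputation reading of the soft background labels is a
  reconstruction; the original single-engine formulation is not publicly
  specified.
- No spatial random effects: residual spatial autocorrelation beyond the
  expansion terms is not modelled.
- No edge-corrected or adaptive KDE; no target-group background; no
  threshold-optimization metrics (kappa/TSS) — all outside scope.

## Problem sizes used in the shipped checks

Oracle and closed-form checks run at n ≤ 100 in seconds. Recovery checks:
ML-oracle agreement at n = 1000; CI coverage over 60 replicates at
n = 500; simulation-based calibration over 48 replicates at n = 400;
flagship selection/coverage over 10 generated systems. All seeds are fixed
in the test source; the acceptance script regenerates its systems from the
command-line seed alone.
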