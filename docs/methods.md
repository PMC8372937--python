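# Methods

## The model

`coveychoice` implements a hierarchical Bayesian conditional multinomial
logit — a discrete-choice model of resource selection for animals
observed in social groups ("coveys") during fall and winter.  Each
selection event is a *choice set*: the location the covey actually used,
paired with three locations that were available to it at the same time
(sampled 50–400 m away at a uniform random azimuth, 400 m being a 90%
quantile of between-resighting movements).  Every alternative carries
nine covariates: four measured at the point (percent forbs FB, grass GS,
bare ground BR in a 0.50-m² quadrat; visual obstruction VO from a 2-m
pole read in the four cardinal directions) plus stem count SC (woody
stems > 1 m tall within 5 m), and four landscape covariates in a 50-m
buffer (proportion native grass NG, proportion burned/grazed within 12
months PG, distance to nearest tree TD, woody edge density WE).  An
NG × PG interaction is derived from the raw product.

The utility of alternative *j* in choice set *i* of covey *c*, season
*s*, is the linear score

```
U_ij = Σ_k β_{c,s,k} · x_ijk
```

over covariates standardized to pooled mean 0, sd 1 (pooled over all
alternatives, used and available, once across the dataset — the only
pooling that keeps within-set contrasts meaningful).  The probability
that the used location was chosen is the softmax of the four utilities.
Because the model conditions on the choice set, any covariate constant
within a set drops out of the likelihood; an explicit null model (no
covariates) therefore assigns probability exactly 1/4 to every
alternative.

Covey-level coefficients are partially pooled through season-specific
population distributions,

```
β_{c,s,k} ~ Normal(μ_{s,k}, σ_{s,k}²),
```

with season binary (November = fall = 0, December–January = winter = 1).
Priors: μ ~ Normal(0, 10²) — the vague precision-0.01 normal — and
σ ~ half-Normal(1).

## Why the σ prior is unit-scale, not diffuse

With ~650 choice sets over ~67 coveys and two seasons, each covey-season
contributes only ≈ 4–6 sets while its coefficient vector has ~6
components.  Such a block is almost surely *separable*: coefficient
directions exist along which the block's likelihood increases
monotonically to a plateau (every choice "classified" correctly).  The
marginal likelihood of σ then increases toward the plateau ceiling, so a
diffuse prior (e.g. half-Normal(5)) leaves σ unidentified and drags the
population means outward with it.  We verified this against an exact
2-D quadrature of the posterior on a small fixture (1 covariate, 15
coveys × 4 sets): the sampler reproduces the exact posterior to within
Monte-Carlo error, and the outward drift is a property of the posterior
under the diffuse prior, not a sampler artifact.  A data-rich check (30
sets per covey-season) recovers the generating values exactly,
confirming the likelihood is correctly specified.  A unit-scale
half-Normal on standardized covariates is the standard
weakly-informative remedy and is the default; the scale is a config
knob (`McmcConfig.prior_sigma_sd`), and users fitting datasets with
many sets per covey can safely relax it.

Even with the unit-scale prior, conditional frequentist coverage of the
85% CRIs at a *fixed* extreme truth sits somewhat below nominal at this
study scale (≈ 70–90% per parameter in our replicate experiments) —
small-group separation biases coefficient magnitudes slightly outward.
This is inherent to the design (4 observations per latent vector), not
to the implementation, and should be kept in mind when interpreting
effect sizes from data of this shape.

## Sampling

The posterior is explored with adaptive Metropolis-within-Gibbs,
compiled with numba:

* blocked Gaussian random-walk updates of each covey-season coefficient
  vector (blocks are conditionally independent given the
  hyperparameters; proposal steps scale with the current σ per
  component);
* an exact conjugate Gibbs draw for each population mean;
* a log-scale random walk for each population sd (half-Normal prior plus
  Jacobian);
* ancillarity–sufficiency interweaving moves that hold the standardized
  deviations (β − μ)/σ fixed: a joint translation of μ with its entire
  season's coefficient field, and a joint rescale of σ with the
  coefficient spread.  These are what make the centred parameterization
  mix: on likelihood plateaus the joint translation is cheap to accept,
  so the chain traverses the flat directions of μ quickly.

Per iteration the sampler runs 4 coefficient sweeps, 2 σ sweeps and 6
interweaving passes; proposal scales adapt by Robbins–Monro during
burn-in only (targets 0.234 for vector blocks, 0.44 for scalars, 0.3
for season-joint moves) and are frozen afterwards, so the post-burn-in
chain is a valid Markov chain.  Chains initialize over-dispersed
(μ, β ~ N(0, 2.5²), log σ ~ N(0, 0.5²)) and re-draw on a non-finite
start.  The default protocol is 4 chains × 100,000 iterations with a
10,000-iteration burn-in and thinning of 50; retained draws per chain
are `(n_iterations − burn_in) // thin`.  Fits are reproducible for a
fixed seed (chain *c* uses `default_rng([seed, c])`, which seeds the
compiled kernel).

Non-hierarchical fits (`random_coefficients=False`) share one
coefficient vector per season and use a plain blocked random walk; this
variant is also the oracle target for grid-quadrature checks, since its
posterior is low-dimensional and integrable densely.

Convergence is summarized by the classic Gelman–Rubin potential scale
reduction factor, R̂ = √((n−1)/n + B/(nW)), flagged at ≥ 1.1.  (The
rank-normalized split-R̂ of modern samplers is stricter; the classic
form is used so the identical-chains limit √((n−1)/n) and hand-computed
fixtures are exact.)  Non-converged fits are reported, never silently
accepted.

## Posterior summaries and prediction

Each parameter is reported as the posterior mean (PM), the equal-tailed
85% credible interval (7.5th–92.5th linear-interpolation percentiles),
and the posterior probability of a positive/negative effect, coded
"+"/"−" when it exceeds 0.85.

Model comparison uses WAIC with the variance form of the effective
parameter count: per choice set, lppd_i = log posterior-mean likelihood
and pWAIC_i = posterior variance of the log-likelihood; WAIC =
−2 Σ(lppd_i − pWAIC_i).  Models within 2 WAIC units of the best are
competitive; a competitive model is dropped as uninformative when a
competitive model with strictly fewer terms shares at least one term
with it.

Relative-probability-of-selection curves sweep one covariate of a
hypothetical focal alternative over its observed range (original units,
back-transformed through the stored standardization constants) while
the three reference alternatives — and all other covariates — sit at
the pooled means.  Only the focal standardized value z then differs, so
per posterior draw of the season's population mean m the relative
probability is exp(mz)/(exp(mz) + 3); at the covariate mean it is
exactly 1/4.  The curve reports the pointwise posterior mean and 85%
CRI, plus companion curves at the 7.5% and 92.5% posterior values of
the focal coefficient.  Uncertainty propagates population-mean draws
only (not covey-level σ): the curves are population-level relative
probabilities.

## Landscape covariates

Vegetation-height rasters (e.g. 3.6-m LiDAR canopy-height models) are
classified as shrub on [0.7, 3.5) m and tree on [3.5, 40] m (half-open
at the shared boundary so no cell is both; taller outliers are open).
Metrics use planar metric coordinates and simple, oracle-checkable
conventions: buffer membership is cell-center-in-disc; woody edge
density sums the lengths of internal shrub/tree-vs-other cell
boundaries whose midpoints fall in the disc, divided by the full disc
area in hectares (raster borders are not edges — the outside class is
unknown); distance-to-class is measured to cell centers, zero inside a
matching cell, and an absent class raises rather than returning a
sentinel.  Users comparing against polygon-based GIS outputs should
expect half-cell-scale differences from the center-based conventions.
Native-grass and managed layers are accepted as caller-supplied masks;
the modelling modules consume covariates directly, so the raster
pathway is optional.  Raster I/O is the ESRI ASCII grid text format.

## The synthetic generator

The generator emulates the study's structure: 67 coveys, 650 choice
sets (1 used + 3 available), ~40% fall, every covey contributing at
least one set.  Covariate marginals are bounded families calibrated to
the field ranges (truncated normals for the percent covers and VO;
negative-binomial counts for SC on [0, 1000]; betas for NG and PG;
truncated exponential for TD on [0, 310] m; clipped gamma for WE on
[0, 2100] m/ha), with season-specific means matching the observed
fall/winter differences.  Truth population means default to the fitted
effect-size regime (GS fall −3.77, VO winter 4.59, SC winter 3.35, TD
winter −3.28, …) and the truth population sd defaults to 1.0 on the
standardized scale — a moderate between-covey heterogeneity chosen
once, since the field study reports no covey-level variance estimates.
Choices are sampled from the softmax over pooled-standardized
covariates, matching the fitted model's scale, and selection events are
independent.  A `within_set_rho` knob injects Gaussian-copula
correlation among a set's four alternatives (default 0; no fidelity
claim — real used/available points 50–400 m apart are spatially
correlated in ways the generator does not model).  A `TruthRecord`
stores every latent quantity (μ, σ, all covey-season coefficients,
chosen indices, standardization constants, seed) so utilities and
choice probabilities can be recomputed exactly.

What passing recovery tests on this generator shows: the estimator
correctly inverts its own data-generating process at the study's scale
and effect sizes.  What it does not show: robustness to spatial
autocorrelation, telemetry error, covey mis-assignment, or
non-Normal coefficient heterogeneity, none of which the generator
emulates.

## Problem sizes used in the automated checks

The test suite fits 20 replicate study-scale datasets (and the
acceptance script 5) with a scaled-down protocol — 4 chains × 5,000
iterations, 1,000 burn-in, thinning 5 (800 retained draws per chain) —
which the convergence diagnostics show is sufficient at this problem
size (population R̂ ≤ ~1.05).  Grid-quadrature comparisons use a
200-set, single-covariate fixture with 3,001 grid points; exhaustive
landscape oracles run on rasters up to 50 × 50 cells.

## Known limitations

* Conditional coverage of CRIs at fixed extreme truths is slightly
  below nominal at ~4 sets per covey-season (see the σ-prior section).
* The ΔWAIC < 2 filter implements term-overlap simplicity, not nested
  model testing; disjoint competitive models are both retained.
* Quadratic terms are supported (`"GS^2"`) but off by default; with
  field-scale data such models may fail to converge, and the
  diagnostics will say so rather than the fit being rejected outright.
* Azimuths for available-location sampling are continuous rather than
  integer-valued; at study scale the difference is immaterial.
* Coordinates are assumed planar metric; no geographic CRS handling.
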