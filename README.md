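# coveychoice

Hierarchical Bayesian discrete-choice (conditional multinomial logit)
resource-selection analysis for covey-based wildlife telemetry.

## The problem

Fall/winter resource selection of northern bobwhite is studied by
comparing where a covey actually was (the *used* location) with where it
could have been (three *available* locations sampled 50–400 m away at
random azimuths).  Each used + available quadruple forms a **choice
set**; the composition of choice sets changes over time, which is
exactly what a conditional (discrete-choice) model handles: only
within-set covariate contrasts matter, and anything constant within a
set drops out.

The utility of alternative *j* in choice set *i* of covey *c* is

> U_ij = β₁c·FB + β₂c·GS + β₃c·BR + β₄c·VO + β₅c·SC + β₆c·NG + β₇c·PG +
> β₈c·NG×PG + β₉c·TD + β₁₀c·WE

over standardized covariates (percent forbs, grass, bare ground in a
0.50-m² frame; Robel-pole visual obstruction; woody stem count; and
50-m-buffer proportions of native grass and burned/grazed ground,
distance to tree, woody edge density).  The probability that the used
location was chosen is the softmax

> P(j) = exp(U_j) / Σ_k exp(U_k),

and covey-level coefficients arise from season-specific population
distributions β_{c,s,k} ~ N(μ_{s,k}, σ²_{s,k}) (fall = November,
winter = December–January), with vague Normal(0, 10²) priors on μ and a
weakly-informative half-Normal(1) prior on σ.  Posteriors are sampled
with an adaptive, interweaved Metropolis-within-Gibbs sampler (numba
compiled), checked with the Gelman–Rubin statistic, compared by WAIC
with a ΔWAIC < 2 competitive-model filter, and turned into
relative-probability-of-selection curves.  The package also computes
the landscape covariates themselves (percent cover, woody edge
density, distance to tree) from vegetation-height rasters, and ships a
truth-tracked synthetic data generator for recovery testing.

Who this is for: quantitative wildlife ecologists fitting
used–available designs with grouped animals, and anyone needing a
tested, self-contained reference implementation of hierarchical
conditional-logit RSF machinery.

## Worked example

```python
import coveychoice as cc

config = cc.GeneratorConfig(n_coveys=30, n_sets=300)
sets, rows, truth = cc.generate_dataset(config, seed=42)

spec = cc.ModelSpec(("GS", "VO", "SC", "NG", "TD", "WE"))
mcmc = cc.McmcConfig(n_chains=4, n_iterations=5000, burn_in=1000,
                     thin=5, seed=7)
draws = cc.sample_posterior(sets, spec, mcmc)

summary = cc.summarize_posterior(draws)
print(summary.loc[draws.population_names()[:12]].round(2))

rhat = cc.gelman_rubin(draws)
print(f"max population R-hat: {rhat[draws.population_names()].max():.3f}")

waic = cc.compute_waic(draws, sets)
null = cc.null_waic(len(sets))
print(f"WAIC {waic.waic:.1f} vs null {null.waic:.1f}")

curve = cc.relative_probability_curve(draws, sets, "VO", "winter")
print(f"VO winter curve: {curve.mean[0]:.3f} at VO={curve.grid[0]:.0f} "
      f"-> {curve.mean[-1]:.3f} at VO={curve.grid[-1]:.0f}")
```

prints

```
                 PM  cri_lo  cri_hi  prop_pos  prop_neg support
mu[GS,fall]   -3.89   -5.16   -2.76      0.00      1.00       -
mu[VO,fall]    2.99    2.11    4.02      1.00      0.00       +
mu[SC,fall]    1.92    1.20    2.73      1.00      0.00       +
mu[NG,fall]   -0.21   -0.81    0.35      0.31      0.69       0
mu[TD,fall]   -0.18   -0.84    0.45      0.35      0.65       0
mu[WE,fall]    1.62    0.91    2.43      1.00      0.00       +
mu[GS,winter] -0.37   -0.82    0.03      0.10      0.90       -
mu[VO,winter]  4.36    3.44    5.41      1.00      0.00       +
mu[SC,winter]  2.76    2.06    3.57      1.00      0.00       +
mu[NG,winter] -0.45   -0.85   -0.08      0.04      0.96       -
mu[TD,winter] -3.02   -3.97   -2.21      0.00      1.00       -
mu[WE,winter]  0.77    0.36    1.17      1.00      0.00       +
max population R-hat: 1.007
WAIC 300.0 vs null 831.8
VO winter curve: 0.000 at VO=0 -> 1.000 at VO=99
```

Reading the output: `PM` is the posterior mean of each season-specific
population coefficient on the standardized scale, with its equal-tailed
85% credible interval and the posterior probability of a
positive/negative effect ("+"/"−" when above 0.85).  Here the generator's
truth (e.g. grass −3.77 in fall, visual obstruction 4.59 and tree
distance −3.28 in winter) is recovered: strong avoidance of grassy
points in fall, strong selection for visual obstruction and woody stems,
selection for locations nearer trees in winter.  R-hat < 1.1 on all
population parameters indicates converged chains; the fitted model beats
the null (all-quarter probabilities) by > 500 WAIC units; the selection
curve shows the relative probability of choosing a location rising from
~0 to ~1 across the observed visual-obstruction range in winter.

A command-line interface mirrors the library:
`coveychoice simulate | prepare | fit | rank | predict | covariates`
(see `coveychoice --help`); `covariates` reads vegetation-height rasters
in ESRI ASCII grid format and a point CSV and writes per-point percent
covers, woody edge density, and tree distance.

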