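"""Hierarchical Bayesian conditional multinomial-logit estimation.

The model.  Each choice set offers four alternatives (one used, three
available) to a covey.  The utility of alternative ``j`` in set ``i`` of
covey ``c`` during season ``s`` is the linear score

    U_ij = sum_k beta_{c,s,k} * x_ijk

over standardized covariates ``x``; the probability that the used location
was chosen is the softmax of the four utilities (a conditional logit, so
set-constant covariates drop out).  Covey-level coefficients arise from
season-specific population distributions

    beta_{c,s,k} ~ Normal(mu_{s,k}, sigma_{s,k}^2)

with a vague prior mu ~ Normal(0, 10^2) (the precision-0.01 normal) and a
weakly-informative prior sigma ~ half-Normal(1).  The sigma prior scale
matters: with only a handful of choice sets per covey-season the
coefficient blocks are separable (the set likelihood plateaus in whole
directions of coefficient space), so a diffuse sigma prior leaves the
population sd unidentified and inflates the population means; a unit-scale
half-Normal on standardized covariates is the standard weakly-informative
remedy (see the methods note for the quadrature analysis).  Season is
binary: fall (November) = 0, winter (December-January) = 1.

Sampling.  The posterior is explored with an adaptive Metropolis-within-
Gibbs scheme: joint random-walk updates of each covey-season coefficient
block (conditionally independent across blocks, so all blocks update in one
vectorized step), an exact conjugate Gibbs draw for each population mean,
and a log-scale random-walk for each population sd.  Because each
covey-season contributes only a handful of choice sets, the centred
parameterization alone mixes slowly (the population mean is tightly coupled
to the coefficient field), so every iteration adds repeated
ancillarity-sufficiency interweaving moves that hold the standardized
deviations (beta - mu)/sigma fixed: a joint translation of mu together
with all of its season's coefficients, and a joint rescale of sigma with
the coefficient spread.  Proposal scales adapt by Robbins-Monro during
burn-in only and are frozen afterwards.  Any correct MCMC would do; this
one is chosen because the blocked structure vectorizes across the ~134
covey-season groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import halfnorm, norm

from .data import ALL_TERMS, ChoiceSet, StandardizationParams, design_matrix, \
    fit_standardization, vif_screen

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "Design",
    "PosteriorDraws",
    "build_design",
    "choice_set_loglik",
    "log_posterior",
    "sample_posterior",
    "gelman_rubin",
    "summarize_posterior",
]

SEASON_LABELS = ("fall", "winter")

LOG_QUARTER = float(np.log(0.25))


def _base_term(term: str) -> str:
    return term[:-2] if term.endswith("^2") else term


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the utility, and the hierarchy switches.

    ``terms`` may include any of FB, GS, BR, VO, SC, NG, PG, NG_PG, TD, WE
    plus quadratic forms written ``"GS^2"`` (off by default; supplied
    explicitly when wanted).  The empty tuple is the explicit null model:
    no free parameters, every alternative has probability 1/4.

    ``random_coefficients`` draws a coefficient vector per covey-season
    from the population distribution; when off, all coveys share the
    population mean (non-hierarchical).  ``seasonal`` fits separate fall
    and winter population distributions (the default).
    """

    terms: tuple[str, ...]
    random_coefficients: bool = True
    seasonal: bool = True
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        for t in self.terms:
            if _base_term(t) not in ALL_TERMS:
                raise ValueError(f"unknown model term {t!r}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate model terms")
        if "NG_PG" in self.terms and not {"NG", "PG"} <= set(self.terms):
            raise ValueError("NG_PG requires NG and PG in the model")

    @property
    def is_null(self) -> bool:
        return len(self.terms) == 0

    @property
    def label(self) -> str:
        return self.name or ("null" if self.is_null else "+".join(self.terms))


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings; defaults follow the 4 x 100k / 10k / 50 protocol.

    ``n_iterations`` is the total per chain including burn-in, so the
    retained count per chain is (n_iterations - burn_in) // thin.
    ``prior_mu_sd`` is the sd of the Normal(0, .) prior on population means
    (10 corresponds to the vague precision-0.01 normal); ``prior_sigma_sd``
    scales the half-Normal prior on population sds (unit scale by default,
    weakly informative on standardized covariates -- a diffuse choice is
    unidentified here; see the module docstring).
    """

    n_chains: int = 4
    n_iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 50
    prior_mu_sd: float = 10.0
    prior_sigma_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_iterations <= self.burn_in:
            raise ValueError("n_iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (self.prior_mu_sd > 0 and self.prior_sigma_sd > 0):
            raise ValueError("prior scales must be positive (proper priors)")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class Design:
    """Standardized design arrays for fitting.

    ``X`` is (n_sets, 4, K); ``group_idx`` maps each set to its covey-season
    group (groups in sorted (covey, season) order); ``group_season`` gives
    each group's season index.
    """

    X: np.ndarray
    used_idx: np.ndarray
    group_idx: np.ndarray
    group_labels: list[tuple[object, int]]
    group_season: np.ndarray
    set_season: np.ndarray
    n_seasons: int
    terms: tuple[str, ...]
    params: StandardizationParams | None

    @property
    def n_sets(self) -> int:
        return len(self.used_idx)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


def build_design(sets: list[ChoiceSet], spec: ModelSpec,
                 params: StandardizationParams | None = None,
                 standardize: bool = True) -> Design:
    """Assemble the fitting arrays, standardizing covariates by default."""
    K = len(spec.terms)
    n_seasons = 2 if spec.seasonal else 1
    if not sets:
        return Design(np.empty((0, 4, K)), np.empty(0, int), np.empty(0, int),
                      [], np.empty(0, int), np.empty(0, int),
                      n_seasons, spec.terms, params)
    if standardize and params is None and K > 0:
        params = fit_standardization(sets, spec.terms)
    X = design_matrix(sets, spec.terms, params if standardize else None)
    used_idx = np.array([cs.used_index for cs in sets])
    set_season = (np.array([cs.season for cs in sets])
                  if spec.seasonal else np.zeros(len(sets), dtype=int))
    labels = sorted({(cs.covey_id, int(s))
                     for cs, s in zip(sets, set_season)})
    gmap = {lab: g for g, lab in enumerate(labels)}
    group_idx = np.array([gmap[(cs.covey_id, int(s))]
                          for cs, s in zip(sets, set_season)])
    group_season = np.array([s for _, s in labels])
    return Design(X, used_idx, group_idx, labels, group_season,
                  set_season, n_seasons, spec.terms, params)


def _set_logliks(X: np.ndarray, used_idx: np.ndarray, B: np.ndarray
                 ) -> np.ndarray:
    """Per-set log softmax probability of the used alternative.

    ``B`` holds the coefficient vector of each set's covey-season, shape
    (n_sets, K).  Max-subtraction keeps the softmax overflow-safe.
    """
    U = np.einsum("nak,nk->na", X, B)
    m = U.max(axis=1)
    lse = m + np.log(np.exp(U - m[:, None]).sum(axis=1))
    return U[np.arange(len(U)), used_idx] - lse


def choice_set_loglik(cs: ChoiceSet, beta, spec: ModelSpec) -> float:
    """Log choice probability of one set's used alternative.

    ``beta`` maps term -> coefficient (or is an array ordered like
    ``spec.terms``) for the set's covey and season; covariates are taken as
    stored (standardize upstream).
    """
    if spec.is_null:
        return LOG_QUARTER
    if isinstance(beta, dict):
        missing = [t for t in spec.terms if t not in beta]
        if missing:
            raise ValueError(f"coefficients missing for terms {missing}")
        b = np.array([beta[t] for t in spec.terms])
    else:
        b = np.asarray(beta, dtype=float)
        if b.shape != (len(spec.terms),):
            raise ValueError("coefficient vector does not match spec terms")
    x = np.array([[a.value(t) for t in spec.terms]
                  for a in cs.alternatives])
    u = x @ b
    m = u.max()
    return float(u[cs.used_index] - (m + np.log(np.exp(u - m).sum())))


def log_posterior(mu: np.ndarray, sigma: np.ndarray | None,
                  beta: np.ndarray | None, design: Design, spec: ModelSpec,
                  mcmc: McmcConfig) -> float:
    """Unnormalized log posterior density, by direct summation.

    Hierarchical: likelihood + sum log N(beta | mu, sigma^2)
    + sum log N(mu | 0, prior_mu_sd^2) + sum log half-N(sigma | prior_sigma_sd).
    Non-hierarchical (sigma and beta None): beta == mu for every covey.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    lp = float(norm.logpdf(mu, 0.0, mcmc.prior_mu_sd).sum())
    if sigma is None:
        B = mu[design.set_season]
        lp += float(_set_logliks(design.X, design.used_idx, B).sum())
        return lp
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if (sigma <= 0).any():
        return -np.inf
    lp += float(halfnorm.logpdf(sigma, scale=mcmc.prior_sigma_sd).sum())
    mu_g = mu[design.group_season]
    sig_g = sigma[design.group_season]
    lp += float(norm.logpdf(beta, mu_g, sig_g).sum())
    if design.n_sets:
        B = beta[design.group_idx]
        lp += float(_set_logliks(design.X, design.used_idx, B).sum())
    return lp


@dataclass
class PosteriorDraws:
    """Retained MCMC samples: chains x draws x named parameters.

    Population parameters are named ``mu[term,season]`` / ``sigma[term,season]``
    and covey-season coefficients ``beta[covey,term,season]`` (season label
    ``all`` for non-seasonal fits).
    """

    array: np.ndarray
    names: list[str]
    spec: ModelSpec
    mcmc: McmcConfig
    seed: int
    params: StandardizationParams | None
    group_labels: list[tuple[object, int]]
    n_seasons: int

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("parameter names must be unique")
        if self.array.ndim != 3 or self.array.shape[2] != len(self.names):
            raise ValueError("draw array shape inconsistent with names")

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[1]

    def get(self, name: str) -> np.ndarray:
        """(chains, draws) samples of one named parameter."""
        return self.array[:, :, self.names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def population_names(self) -> list[str]:
        return [n for n in self.names if n.startswith(("mu[", "sigma["))]

    def season_label(self, s: int) -> str:
        return SEASON_LABELS[s] if self.n_seasons == 2 else "all"

    def to_inference_data(self):
        """arviz InferenceData view (one variable per named parameter)."""
        import arviz as az

        return az.from_dict({n: self.array[:, :, i]
                             for i, n in enumerate(self.names)})


def _param_names(spec: ModelSpec, design: Design) -> list[str]:
    seasons = (SEASON_LABELS if design.n_seasons == 2 else ("all",))
    names = [f"mu[{t},{seasons[s]}]"
             for s in range(design.n_seasons) for t in spec.terms]
    if spec.random_coefficients:
        names += [f"sigma[{t},{seasons[s]}]"
                  for s in range(design.n_seasons) for t in spec.terms]
        names += [f"beta[{c},{t},{seasons[s]}]"
                  for c, s in design.group_labels for t in spec.terms]
    return names


from numba import njit


@njit(cache=True)
def _group_ll_nb(X, used_idx, group_idx, beta, G):
    """Per-group sums of log softmax probabilities of the used alternatives."""
    N = X.shape[0]
    K = X.shape[2]
    out = np.zeros(G)
    U = np.empty(4)
    for n in range(N):
        g = group_idx[n]
        maxu = -1e300
        for a in range(4):
            acc = 0.0
            for k in range(K):
                acc += X[n, a, k] * beta[g, k]
            U[a] = acc
            if acc > maxu:
                maxu = acc
        sexp = 0.0
        for a in range(4):
            sexp += np.exp(U[a] - maxu)
        out[g] += U[used_idx[n]] - (maxu + np.log(sexp))
    return out


@njit(cache=True)
def _hier_kernel(X, used_idx, group_idx, group_season, S, n_iter, burn_in,
                 thin, tau2, s0, seed, out):
    """One hierarchical chain (see module docstring for the update scheme).

    Update sweeps per iteration: 4 blocked coefficient random walks, exact
    Gibbs for the population means, 2 log-scale sd walks, and 6 interweaving
    (translate + rescale) passes.  Adaptation runs during burn-in only.
    """
    np.random.seed(seed)
    K = X.shape[2]
    G = len(group_season)
    n_s = np.zeros(S)
    for g in range(G):
        n_s[group_season[g]] += 1.0

    mu = np.empty((S, K))
    lsig = np.empty((S, K))
    beta = np.empty((G, K))
    ll_group = np.zeros(G)
    for _attempt in range(50):
        for s in range(S):
            for k in range(K):
                mu[s, k] = 2.5 * np.random.standard_normal()
                lsig[s, k] = 0.5 * np.random.standard_normal()
        for g in range(G):
            for k in range(K):
                beta[g, k] = 2.5 * np.random.standard_normal()
        ll_group = _group_ll_nb(X, used_idx, group_idx, beta, G)
        ok = True
        for g in range(G):
            if not np.isfinite(ll_group[g]):
                ok = False
        if ok:
            break

    b_lscale = np.full(G, np.log(0.5))
    s_lscale = np.full((S, K), np.log(0.5))
    tr_lscale = np.full(S, np.log(0.5))
    rs_lscale = np.full(S, np.log(0.3))
    prop = np.empty((G, K))
    eps = np.empty((S, K))
    kept = 0
    for t in range(1, n_iter + 1):
        adapting = t <= burn_in
        gamma = min(0.25, 2.0 / np.sqrt(t))
        # blocked random walk on each covey-season coefficient vector,
        # proposal steps scaled by the current population sd per component
        for _sweep in range(4):
            for g in range(G):
                s = group_season[g]
                step = np.exp(b_lscale[g])
                for k in range(K):
                    sd = np.exp(lsig[s, k])
                    prop[g, k] = beta[g, k] + step * sd * \
                        np.random.standard_normal()
            ll_prop = _group_ll_nb(X, used_idx, group_idx, prop, G)
            for g in range(G):
                s = group_season[g]
                d_prior = 0.0
                for k in range(K):
                    sd = np.exp(lsig[s, k])
                    d_prior += ((beta[g, k] - mu[s, k]) ** 2
                                - (prop[g, k] - mu[s, k]) ** 2) / (2 * sd * sd)
                log_r = ll_prop[g] - ll_group[g] + d_prior
                if np.log(np.random.random()) < log_r:
                    for k in range(K):
                        beta[g, k] = prop[g, k]
                    ll_group[g] = ll_prop[g]
                    if adapting:
                        b_lscale[g] += gamma * (1.0 - 0.234)
                elif adapting:
                    b_lscale[g] -= gamma * 0.234
        # exact conjugate draw for each population mean
        for s in range(S):
            for k in range(K):
                sb = 0.0
                for g in range(G):
                    if group_season[g] == s:
                        sb += beta[g, k]
                var = np.exp(2.0 * lsig[s, k])
                prec = n_s[s] / var + 1.0 / tau2
                mean = (sb / var) / prec
                mu[s, k] = mean + np.random.standard_normal() / np.sqrt(prec)
        # log-scale random walk for each population sd
        for _sweep in range(2):
            for s in range(S):
                for k in range(K):
                    ssq = 0.0
                    for g in range(G):
                        if group_season[g] == s:
                            ssq += (beta[g, k] - mu[s, k]) ** 2
                    l_cur = lsig[s, k]
                    l_new = l_cur + np.exp(s_lscale[s, k]) * \
                        np.random.standard_normal()
                    t_cur = (-n_s[s] * l_cur - ssq / (2 * np.exp(2 * l_cur))
                             - np.exp(2 * l_cur) / (2 * s0 * s0) + l_cur)
                    t_new = (-n_s[s] * l_new - ssq / (2 * np.exp(2 * l_new))
                             - np.exp(2 * l_new) / (2 * s0 * s0) + l_new)
                    if np.log(np.random.random()) < t_new - t_cur:
                        lsig[s, k] = l_new
                        if adapting:
                            s_lscale[s, k] += gamma * (1.0 - 0.44)
                    elif adapting:
                        s_lscale[s, k] -= gamma * 0.44
        for _rep in range(6 if G else 0):
            # interweaving move 1: translate mu with its season's whole
            # coefficient field, holding the deviations beta - mu fixed
            for s in range(S):
                for k in range(K):
                    eps[s, k] = np.exp(tr_lscale[s]) * \
                        np.random.standard_normal()
            for g in range(G):
                s = group_season[g]
                for k in range(K):
                    prop[g, k] = beta[g, k] + eps[s, k]
            ll_prop = _group_ll_nb(X, used_idx, group_idx, prop, G)
            for s in range(S):
                d = 0.0
                for g in range(G):
                    if group_season[g] == s:
                        d += ll_prop[g] - ll_group[g]
                for k in range(K):
                    m_new = mu[s, k] + eps[s, k]
                    d += (mu[s, k] ** 2 - m_new ** 2) / (2 * tau2)
                if np.log(np.random.random()) < d:
                    for k in range(K):
                        mu[s, k] += eps[s, k]
                    for g in range(G):
                        if group_season[g] == s:
                            for k in range(K):
                                beta[g, k] = prop[g, k]
                            ll_group[g] = ll_prop[g]
                    if adapting:
                        tr_lscale[s] += gamma * (1.0 - 0.3)
                elif adapting:
                    tr_lscale[s] -= gamma * 0.3
            # interweaving move 2: rescale sigma with the coefficient
            # spread, holding the standardized deviations fixed
            for s in range(S):
                for k in range(K):
                    eps[s, k] = np.exp(rs_lscale[s]) * \
                        np.random.standard_normal()
            for g in range(G):
                s = group_season[g]
                for k in range(K):
                    prop[g, k] = mu[s, k] + (beta[g, k] - mu[s, k]) * \
                        np.exp(eps[s, k])
            ll_prop = _group_ll_nb(X, used_idx, group_idx, prop, G)
            for s in range(S):
                d = 0.0
                for g in range(G):
                    if group_season[g] == s:
                        d += ll_prop[g] - ll_group[g]
                for k in range(K):
                    l_new = lsig[s, k] + eps[s, k]
                    d += (np.exp(2 * lsig[s, k]) - np.exp(2 * l_new)) \
                        / (2 * s0 * s0) + eps[s, k]
                if np.log(np.random.random()) < d:
                    for k in range(K):
                        lsig[s, k] += eps[s, k]
                    for g in range(G):
                        if group_season[g] == s:
                            for k in range(K):
                                beta[g, k] = prop[g, k]
                            ll_group[g] = ll_prop[g]
                    if adapting:
                        rs_lscale[s] += gamma * (1.0 - 0.3)
                elif adapting:
                    rs_lscale[s] -= gamma * 0.3
        if t > burn_in and (t - burn_in) % thin == 0:
            col = 0
            for s in range(S):
                for k in range(K):
                    out[kept, col] = mu[s, k]
                    col += 1
            for s in range(S):
                for k in range(K):
                    out[kept, col] = np.exp(lsig[s, k])
                    col += 1
            for g in range(G):
                for k in range(K):
                    out[kept, col] = beta[g, k]
                    col += 1
            kept += 1
    return kept


def _run_chain_hier(design: Design, mcmc: McmcConfig, rng) -> np.ndarray:
    S, K, G = design.n_seasons, len(design.terms), design.n_groups
    out = np.empty((mcmc.n_retained, S * K * 2 + G * K))
    seed = int(rng.integers(2 ** 31))
    X = np.ascontiguousarray(design.X, dtype=np.float64)
    kept = _hier_kernel(X, design.used_idx.astype(np.int64),
                        design.group_idx.astype(np.int64),
                        design.group_season.astype(np.int64), S,
                        mcmc.n_iterations, mcmc.burn_in, mcmc.thin,
                        mcmc.prior_mu_sd ** 2, mcmc.prior_sigma_sd,
                        seed, out)
    return out[:kept]


def _run_chain_pooled(design: Design, mcmc: McmcConfig, rng) -> np.ndarray:
    """Non-hierarchical chain: one shared coefficient vector per season."""
    S, K = design.n_seasons, len(design.terms)
    tau2 = mcmc.prior_mu_sd ** 2

    def season_logliks(mu):
        if design.n_sets == 0:
            return np.zeros(S)
        ll = _set_logliks(design.X, design.used_idx, mu[design.set_season])
        return np.bincount(design.set_season, weights=ll, minlength=S)

    mu = rng.normal(0.0, 2.5, (S, K))
    ll_season = season_logliks(mu)
    lscale = np.full(S, np.log(0.5))
    out = np.empty((mcmc.n_retained, S * K))
    kept = 0
    for t in range(1, mcmc.n_iterations + 1):
        gamma = min(0.25, 2.0 / np.sqrt(t))
        prop = mu + np.exp(lscale)[:, None] * rng.standard_normal((S, K))
        # seasons are independent blocks: likelihood and prior separate by s
        ll_prop = season_logliks(prop)
        pr_cur = (-mu ** 2 / (2 * tau2)).sum(axis=1)
        pr_prop = (-prop ** 2 / (2 * tau2)).sum(axis=1)
        acc = np.log(rng.random(S)) < (ll_prop + pr_prop) - (ll_season + pr_cur)
        mu[acc] = prop[acc]
        ll_season[acc] = ll_prop[acc]
        if t <= mcmc.burn_in:
            lscale += gamma * (acc.astype(float) - 0.3)
        if t > mcmc.burn_in and (t - mcmc.burn_in) % mcmc.thin == 0:
            out[kept] = mu.ravel()
            kept += 1
    return out[:kept]


def sample_posterior(data, spec: ModelSpec, mcmc: McmcConfig = McmcConfig(),
                     params: StandardizationParams | None = None,
                     check_vif: bool = True) -> PosteriorDraws:
    """Draw from the posterior of all population and covey-level parameters.

    ``data`` is a list of validated ChoiceSets (standardized internally,
    pooled over all alternatives) or a pre-built :class:`Design`.  Chains
    run sequentially with over-dispersed initial values; the result is
    reproducible for a fixed ``mcmc.seed``.
    """
    if spec.is_null:
        raise ValueError("the null model has no parameters to sample")
    if isinstance(data, Design):
        design = data
    else:
        design = build_design(data, spec, params=params)
        if check_vif and len(spec.terms) >= 2 and len(data) >= 2:
            try:
                _, ok = vif_screen(data, spec.terms)
                if not ok:
                    warnings.warn(
                        "model terms fail the VIF < 2.5 collinearity screen",
                        stacklevel=2)
            except ValueError:
                pass
    seed = mcmc.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2 ** 31))
    runner = _run_chain_hier if spec.random_coefficients else _run_chain_pooled
    chains = [runner(design, mcmc, np.random.default_rng([seed, c]))
              for c in range(mcmc.n_chains)]
    array = np.stack(chains)
    return PosteriorDraws(array, _param_names(spec, design), spec, mcmc,
                          seed, design.params, design.group_labels,
                          design.n_seasons)


def gelman_rubin(draws: PosteriorDraws | np.ndarray, names=None) -> pd.Series:
    """Potential scale reduction factor (classic between/within form).

    For m >= 2 chains of n draws each, R-hat = sqrt((n-1)/n + B/(n W)) with
    W the mean within-chain variance and B/n the variance of chain means.
    Identical chains give sqrt((n-1)/n) < 1; well-mixed chains sit near 1,
    and values >= 1.1 flag non-convergence.
    """
    if isinstance(draws, PosteriorDraws):
        arr, names = draws.array, draws.names
    else:
        arr = np.asarray(draws, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if names is None:
            names = [f"p{i}" for i in range(arr.shape[2])]
    m, n = arr.shape[0], arr.shape[1]
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin needs at least 10 retained draws")
    chain_means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)
    ratio = np.where(B_over_n == 0, (n - 1) / n,
                     (n - 1) / n + np.divide(
                         B_over_n, W, out=np.full_like(W, np.inf),
                         where=W > 0))
    return pd.Series(np.sqrt(ratio), index=list(names), name="R_hat")


def summarize_posterior(draws: PosteriorDraws, cri_mass: float = 0.85,
                        support_threshold: float = 0.85) -> pd.DataFrame:
    """Posterior mean, equal-tailed CRI, and sign support per parameter.

    PM is the posterior mean over all chains; the CRI spans the equal-tailed
    (7.5th, 92.5th) percentiles for the default 85% mass (linear-interpolation
    percentiles).  ``prop_pos``/``prop_neg`` give the posterior probability
    of a positive/negative effect; the ``support`` code is "+" or "-" when
    that proportion exceeds the threshold, else "0".
    """
    flat = draws.array.reshape(-1, draws.array.shape[2])
    if flat.size == 0:
        raise ValueError("no posterior draws to summarize")
    lo_q, hi_q = 100 * (1 - cri_mass) / 2, 100 * (1 + cri_mass) / 2
    pm = flat.mean(axis=0)
    lo, hi = np.percentile(flat, [lo_q, hi_q], axis=0)
    prop_pos = (flat > 0).mean(axis=0)
    prop_neg = (flat < 0).mean(axis=0)
    support = np.where(prop_pos > support_threshold, "+",
                       np.where(prop_neg > support_threshold, "-", "0"))
    return pd.DataFrame(
        {"PM": pm, "cri_lo": lo, "cri_hi": hi,
         "prop_pos": prop_pos, "prop_neg": prop_neg, "support": support},
        index=draws.names)
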