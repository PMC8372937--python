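"""Synthetic choice-set data with known truth for recovery testing.

The generator reproduces the statistical structure the analysis assumes:
~67 coveys contributing ~650 choice sets split ~40/60 between fall
(November) and winter (December-January); per-covariate marginal
distributions bounded and centred like the field data (percent-cover
covariates as truncated normals, stem counts as negative-binomial counts,
tree distance as a truncated exponential, edge density as a clipped gamma);
season-specific population coefficient distributions; covey-season
coefficient vectors drawn from them; and the used alternative of every set
sampled from the conditional-logit softmax over pooled-standardized
covariates.  Every latent quantity is recorded in a TruthRecord so that
any utility or choice probability can be recomputed exactly.

The default truth population means sit in the fitted effect-size regime
(e.g. grass fall -3.77, visual obstruction winter 4.59, stem count winter
3.35, tree distance winter -3.28 on the standardized scale); the default
population sd is 1.0 for every covariate and season.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import COVARIATES, ChoiceSet, assemble_choice_sets

__all__ = [
    "Marginal",
    "GeneratorConfig",
    "TruthRecord",
    "default_marginals",
    "DEFAULT_TRUTH_MU",
    "draw_covey_coefficients",
    "simulate_choice_sets",
    "simulate_choices",
    "generate_dataset",
]

#: default truth population means (standardized scale) per (covariate, season)
DEFAULT_TRUTH_MU = {
    ("GS", 0): -3.77, ("GS", 1): -0.25,
    ("VO", 0): 2.48, ("VO", 1): 4.59,
    ("SC", 0): 2.67, ("SC", 1): 3.35,
    ("NG", 0): 0.21, ("NG", 1): -0.29,
    ("TD", 0): -0.92, ("TD", 1): -3.28,
    ("WE", 0): 1.37, ("WE", 1): 0.87,
}


@dataclass(frozen=True)
class Marginal:
    """A bounded covariate marginal: frozen scipy distribution + clip bounds."""

    dist: object
    lo: float
    hi: float
    integer: bool = False

    def sample_from_uniform(self, u: np.ndarray) -> np.ndarray:
        x = np.clip(self.dist.ppf(u), self.lo, self.hi)
        return np.round(x) if self.integer else x


def _truncnorm(mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return Marginal(stats.truncnorm(a, b, loc=mean, scale=sd), lo, hi)


def _beta(mean, nu, lo=0.0, hi=1.0):
    return Marginal(stats.beta(mean * nu, (1 - mean) * nu), lo, hi)


def _nbinom(mean, size, hi):
    # gamma-Poisson counts; size is the overdispersion shape
    return Marginal(stats.nbinom(size, size / (size + mean)), 0.0, hi,
                    integer=True)


def _truncexpon(scale, hi):
    return Marginal(stats.truncexpon(hi / scale, scale=scale), 0.0, hi)


def _gamma(mean, shape, hi):
    return Marginal(stats.gamma(shape, scale=mean / shape), 0.0, hi)


def default_marginals() -> dict:
    """Per-(covariate, season) marginals centred on the field ranges.

    Keyed (covariate, season) with fall = 0, winter = 1.  Percent covers and
    visual obstruction are truncated normals on [0, 100]; the 50-m
    proportions are betas on [0, 1]; stem counts are negative-binomial on
    [0, 1000]; tree distance a truncated exponential on [0, 310] m; edge
    density a gamma clipped to [0, 2100] m/ha.
    """
    return {
        ("GS", 0): _truncnorm(39.7, 28.0, 0, 100),
        ("GS", 1): _truncnorm(29.4, 25.0, 0, 100),
        ("FB", 0): _truncnorm(10.1, 12.0, 0, 100),
        ("FB", 1): _truncnorm(5.7, 8.0, 0, 100),
        ("BR", 0): _truncnorm(9.1, 12.0, 0, 100),
        ("BR", 1): _truncnorm(10.7, 13.0, 0, 100),
        ("VO", 0): _truncnorm(37.8, 27.0, 0, 100),
        ("VO", 1): _truncnorm(21.8, 20.0, 0, 100),
        ("SC", 0): _nbinom(25.5, 0.4, 1000),
        ("SC", 1): _nbinom(15.4, 0.4, 1000),
        ("NG", 0): _beta(0.53, 1.2),
        ("NG", 1): _beta(0.44, 1.2),
        ("PG", 0): _beta(0.51, 1.2),
        ("PG", 1): _beta(0.42, 1.2),
        ("TD", 0): _truncexpon(66.0, 310.0),
        ("TD", 1): _truncexpon(70.0, 310.0),
        ("WE", 0): _gamma(357.0, 1.1, 2100.0),
        ("WE", 1): _gamma(341.0, 1.1, 2100.0),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-structure and truth settings for the synthetic generator.

    Defaults emulate the study conditions: 67 coveys, 650 choice sets with
    3 available locations each, a ~40/60 fall/winter season split, field-
    calibrated covariate marginals, truth population means from
    :data:`DEFAULT_TRUTH_MU` and population sd 1.0.  ``within_set_rho`` is
    an optional Gaussian-copula correlation shared by the four alternatives
    of a set (0 = independent; no fidelity claim is attached to it).
    """

    n_coveys: int = 67
    n_sets: int = 650
    fall_fraction: float = 0.4
    n_available: int = 3
    covariates: tuple[str, ...] = ("GS", "VO", "SC", "NG", "TD", "WE")
    mu: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH_MU))
    sigma: object = 1.0
    marginals: dict = field(default_factory=default_marginals)
    within_set_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_coveys < 1:
            raise ValueError("need at least one covey")
        if self.n_sets < self.n_coveys:
            raise ValueError("need at least one choice set per covey")
        if not 0 <= self.fall_fraction <= 1:
            raise ValueError("fall_fraction must lie in [0, 1]")
        if not 0 <= self.within_set_rho < 1:
            raise ValueError("within_set_rho must lie in [0, 1)")
        for cov in self.covariates:
            for s in (0, 1):
                if (cov, s) not in self.marginals:
                    raise ValueError(f"no marginal configured for {cov!r}")
        for v in self._sigma_values():
            if v < 0:
                raise ValueError("population sd must be non-negative")

    def _sigma_values(self):
        if isinstance(self.sigma, dict):
            return list(self.sigma.values())
        return [float(self.sigma)]

    def sigma_for(self, cov: str, season: int) -> float:
        if isinstance(self.sigma, dict):
            return float(self.sigma[(cov, season)])
        return float(self.sigma)

    def mu_for(self, cov: str, season: int) -> float:
        return float(self.mu.get((cov, season), 0.0))


@dataclass
class TruthRecord:
    """Every latent quantity behind one simulated dataset.

    Holds the realized population means/sds, the covey-season coefficient
    matrix, the chosen-alternative index per set, the pooled
    standardization constants the utilities were computed on, and the seed.
    Together these recompute every utility and choice probability exactly.
    """

    covariates: tuple[str, ...]
    mu: dict
    sigma: dict
    covey_ids: list
    beta: np.ndarray  # (n_coveys, 2, K)
    chosen_index: np.ndarray
    std_mean: dict
    std_sd: dict
    seed: object = None

    def choice_probabilities(self, rows: pd.DataFrame) -> np.ndarray:
        """(n_sets, 4) softmax probabilities implied by the truth."""
        U = self.utilities(rows)
        U -= U.max(axis=1, keepdims=True)
        e = np.exp(U)
        return e / e.sum(axis=1, keepdims=True)

    def utilities(self, rows: pd.DataFrame) -> np.ndarray:
        """(n_sets, 4) utilities on the standardized scale."""
        covey_pos = {c: i for i, c in enumerate(self.covey_ids)}
        n_sets = rows["set_id"].nunique()
        Z = np.stack([
            (rows[c].to_numpy(float) - self.std_mean[c]) / self.std_sd[c]
            for c in self.covariates], axis=1).reshape(n_sets, 4, -1)
        first = rows.groupby("set_id", sort=False).first()
        ci = np.array([covey_pos[c] for c in first["covey_id"]])
        si = first["season"].to_numpy(int)
        return np.einsum("nak,nk->na", Z, self.beta[ci, si, :])


def draw_covey_coefficients(config: GeneratorConfig, seed=None) -> np.ndarray:
    """Draw beta[c, s, k] ~ Normal(mu_{k,s}, sigma_{k,s}^2) independently."""
    rng = np.random.default_rng(seed)
    K = len(config.covariates)
    mu = np.array([[config.mu_for(c, s) for c in config.covariates]
                   for s in (0, 1)])          # (2, K)
    sd = np.array([[config.sigma_for(c, s) for c in config.covariates]
                   for s in (0, 1)])
    return mu[None] + sd[None] * rng.standard_normal((config.n_coveys, 2, K))


def simulate_choice_sets(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Draw the choice-set table (long format) without used flags.

    Every covey receives at least one set; remaining sets are assigned
    uniformly.  Each set gets a season by a Bernoulli(fall_fraction) coin
    and four alternatives whose covariates come from the season's bounded
    marginals (all nine covariates are drawn so the table round-trips
    through validation even when the truth model uses a subset).
    """
    rng = np.random.default_rng(seed)
    n, m = config.n_sets, config.n_coveys
    covey = np.concatenate([np.arange(m), rng.integers(0, m, n - m)])
    rng.shuffle(covey)
    season = (rng.random(n) >= config.fall_fraction).astype(int)
    rows = pd.DataFrame({
        "set_id": np.repeat([f"s{i:04d}" for i in range(n)], 4),
        "covey_id": np.repeat([f"c{c:03d}" for c in covey], 4),
        "date": np.repeat(np.where(season == 0, "2018-11-15", "2018-12-15"), 4),
        "season": np.repeat(season, 4),
    })
    row_season = rows["season"].to_numpy()
    rho = config.within_set_rho
    for cov in COVARIATES:
        if rho > 0:
            z_set = np.repeat(rng.standard_normal(n), 4)
            z_alt = rng.standard_normal(4 * n)
            u = stats.norm.cdf(np.sqrt(rho) * z_set + np.sqrt(1 - rho) * z_alt)
        else:
            u = rng.random(4 * n)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        vals = np.empty(4 * n)
        for s in (0, 1):
            mask = row_season == s
            vals[mask] = config.marginals[(cov, s)].sample_from_uniform(u[mask])
        rows[cov] = vals
    return rows


def simulate_choices(rows: pd.DataFrame, beta: np.ndarray,
                     config: GeneratorConfig, seed=None
                     ) -> tuple[list[ChoiceSet], TruthRecord]:
    """Sample the used alternative of every set from the softmax (Eq. 2 logic).

    Utilities are computed on pooled-standardized covariates (the fitted
    model's scale) with each set using its covey's season-specific
    coefficient vector.  Returns validated ChoiceSets plus the TruthRecord.
    """
    rng = np.random.default_rng(seed)
    covey_ids = sorted(rows["covey_id"].unique())
    if beta.shape != (len(covey_ids), 2, len(config.covariates)):
        raise ValueError(
            f"coefficient array shape {beta.shape} does not cover "
            f"{len(covey_ids)} coveys x 2 seasons x "
            f"{len(config.covariates)} covariates")
    std_mean = {c: float(rows[c].mean()) for c in config.covariates}
    std_sd = {c: float(rows[c].std(ddof=1)) for c in config.covariates}
    truth = TruthRecord(
        covariates=config.covariates,
        mu={(c, s): config.mu_for(c, s)
            for c in config.covariates for s in (0, 1)},
        sigma={(c, s): config.sigma_for(c, s)
               for c in config.covariates for s in (0, 1)},
        covey_ids=covey_ids, beta=beta,
        chosen_index=np.empty(0, int), std_mean=std_mean, std_sd=std_sd,
        seed=seed)
    P = truth.choice_probabilities(rows)
    chosen = (P.cumsum(axis=1) > rng.random((len(P), 1))).argmax(axis=1)
    truth.chosen_index = chosen
    used = np.zeros(len(rows), dtype=bool)
    used[np.arange(len(P)) * 4 + chosen] = True
    rows = rows.assign(used=used)
    return assemble_choice_sets(rows), truth


def generate_dataset(config: GeneratorConfig = GeneratorConfig(), seed=None
                     ) -> tuple[list[ChoiceSet], pd.DataFrame, TruthRecord]:
    """Full pipeline: coefficients, covariates, choices; three seeded stages."""
    ss = np.random.SeedSequence(seed)
    s_beta, s_sets, s_choice = ss.spawn(3)
    beta = draw_covey_coefficients(config, s_beta)
    rows = simulate_choice_sets(config, s_sets)
    sets, truth = simulate_choices(rows, beta, config, s_choice)
    truth.seed = seed
    rows = rows.assign(
        used=[a.used for cs in sets for a in cs.alternatives])
    return sets, rows, truth
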