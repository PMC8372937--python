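"""WAIC model comparison and relative-probability-of-selection curves.

WAIC is computed pointwise over choice sets: lppd_i is the log of the
posterior-mean set likelihood and the effective-parameter term is the
posterior variance of the set log-likelihood (the variance form, pWAIC2),
so WAIC = -2 * sum_i (lppd_i - pWAIC_i).  Models within 2 WAIC units of
the best are competitive; a competitive model is dropped as uninformative
when a simpler competitive model (strictly fewer terms) shares at least
one of its terms.

Selection curves sweep one covariate of a hypothetical focal alternative
over its observed range while the three reference alternatives (and every
other covariate) sit at the pooled covariate means, then evaluate the
softmax per posterior draw of the season's population mean.  Uncertainty
propagates population-mean draws only, giving population-level relative
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import ChoiceSet
from .model import (LOG_QUARTER, Design, ModelSpec, PosteriorDraws,
                    SEASON_LABELS, build_design, _set_logliks)

__all__ = [
    "WaicResult",
    "ModelRanking",
    "SelectionCurve",
    "pointwise_loglik",
    "compute_waic",
    "null_waic",
    "rank_and_filter_models",
    "relative_probability_curve",
]


@dataclass
class WaicResult:
    """Pointwise WAIC decomposition for one fitted model."""

    spec: ModelSpec
    lppd_pointwise: np.ndarray
    p_waic_pointwise: np.ndarray

    @property
    def lppd(self) -> float:
        return float(self.lppd_pointwise.sum())

    @property
    def p_waic(self) -> float:
        return float(self.p_waic_pointwise.sum())

    @property
    def waic(self) -> float:
        return -2.0 * (self.lppd - self.p_waic)


def _beta_per_set(draws: PosteriorDraws, design: Design) -> np.ndarray:
    """(n_total_draws, n_sets, K) coefficient array implied by the draws."""
    flat = draws.array.reshape(-1, draws.array.shape[2])
    idx = {n: i for i, n in enumerate(draws.names)}
    K = len(draws.spec.terms)
    if draws.spec.random_coefficients:
        cols = np.array(
            [[idx[f"beta[{c},{t},{draws.season_label(s)}]"]
              for t in draws.spec.terms]
             for c, s in design.group_labels]).reshape(-1)
        B_group = flat[:, cols].reshape(len(flat), design.n_groups, K)
        return B_group[:, design.group_idx, :]
    cols = np.array(
        [[idx[f"mu[{t},{draws.season_label(s)}]"] for t in draws.spec.terms]
         for s in range(design.n_seasons)]).reshape(-1)
    B_season = flat[:, cols].reshape(len(flat), design.n_seasons, K)
    return B_season[:, design.set_season, :]


def pointwise_loglik(draws: PosteriorDraws, sets: list[ChoiceSet],
                     chunk: int = 256) -> np.ndarray:
    """(n_total_draws, n_sets) set-level log-likelihood matrix."""
    if draws.spec.is_null:
        n = draws.n_chains * draws.n_draws
        return np.full((n, len(sets)), LOG_QUARTER)
    design = build_design(sets, draws.spec, params=draws.params)
    missing = set(design.group_labels) - set(draws.group_labels)
    if missing:
        raise ValueError(
            f"data contain covey-season groups absent from the fit: {missing}")
    B = _beta_per_set(draws, design)
    out = np.empty((B.shape[0], design.n_sets))
    for start in range(0, B.shape[0], chunk):
        b = B[start:start + chunk]
        U = np.einsum("dnk,nak->dna", b, design.X)
        m = U.max(axis=2)
        lse = m + np.log(np.exp(U - m[:, :, None]).sum(axis=2))
        out[start:start + chunk] = (
            U[:, np.arange(design.n_sets), design.used_idx] - lse)
    return out


def waic_terms(ll: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise WAIC terms from a (draws, observations) log-likelihood matrix.

    lppd_i is the log posterior-mean likelihood; the penalty is the
    posterior variance of the log-likelihood (pWAIC2).
    """
    D = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(D)
    p_i = ll.var(axis=0, ddof=1) if D > 1 else np.zeros(ll.shape[1])
    return lppd_i, p_i


def compute_waic(draws: PosteriorDraws, sets: list[ChoiceSet]) -> WaicResult:
    """WAIC with the variance form of the effective-parameter penalty."""
    lppd_i, p_i = waic_terms(pointwise_loglik(draws, sets))
    return WaicResult(draws.spec, lppd_i, p_i)


def null_waic(n_sets: int) -> WaicResult:
    """WAIC of the explicit null model: every set likelihood is exactly 1/4."""
    spec = ModelSpec((), name="null")
    return WaicResult(spec, np.full(n_sets, LOG_QUARTER), np.zeros(n_sets))


@dataclass
class ModelRanking:
    """WAIC-ordered models with the uninformative-competitor filter applied."""

    results: list[WaicResult]
    delta: np.ndarray
    removed: list[bool]
    reasons: list[str]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": [r.spec.label for r in self.results],
            "n_terms": [len(r.spec.terms) for r in self.results],
            "WAIC": [r.waic for r in self.results],
            "dWAIC": self.delta,
            "retained": [not r for r in self.removed],
            "reason": self.reasons,
        })


def rank_and_filter_models(results: list[WaicResult]) -> ModelRanking:
    """Sort by WAIC and drop more complex competitive models.

    A model with dWAIC < 2 is removed when another competitive model has
    strictly fewer terms and shares at least one term with it (the simpler
    model explains the data as well; the extra terms are uninformative).
    """
    term_sets = [frozenset(r.spec.terms) for r in results]
    if len(set(term_sets)) != len(term_sets):
        raise ValueError("duplicate model specifications in ranking")
    order = np.argsort([r.waic for r in results], kind="stable")
    ranked = [results[i] for i in order]
    waics = np.array([r.waic for r in ranked])
    delta = waics - waics[0]
    competitive = [i for i in range(len(ranked)) if delta[i] < 2.0]
    removed, reasons = [], []
    for i, r in enumerate(ranked):
        flag, why = False, ""
        if i in competitive:
            mine = set(r.spec.terms)
            for j in competitive:
                other = ranked[j].spec
                if (len(other.terms) < len(r.spec.terms)
                        and mine & set(other.terms)):
                    flag = True
                    why = (f"more complex competitive model; simpler "
                           f"{other.label} shares terms")
                    break
        removed.append(flag)
        reasons.append(why)
    return ModelRanking(ranked, delta, removed, reasons)


@dataclass
class SelectionCurve:
    """Relative probability of selecting the focal alternative.

    ``grid`` holds covariate values in original units; ``mean``, ``lo``,
    ``hi`` are the pointwise posterior mean and equal-tailed 85% CRI of the
    relative probability, and ``at_lo_coef`` / ``at_hi_coef`` are the
    companion curves evaluated at the 7.5% and 92.5% posterior values of the
    focal coefficient.
    """

    covariate: str
    season: str
    grid: np.ndarray
    grid_std: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    at_lo_coef: np.ndarray
    at_hi_coef: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.covariate: self.grid, "rel_prob_mean": self.mean,
            "cri_lo": self.lo, "cri_hi": self.hi,
            "at_coef_7.5": self.at_lo_coef, "at_coef_92.5": self.at_hi_coef,
        })

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.grid, self.lo, self.hi, alpha=0.3,
                        label="85% CRI")
        ax.plot(self.grid, self.mean, label="posterior mean")
        ax.set_xlabel(self.covariate)
        ax.set_ylabel("relative probability of selection")
        ax.set_title(f"{self.covariate} ({self.season})")
        ax.legend()
        return ax


def _season_index(draws: PosteriorDraws, season) -> str:
    if draws.n_seasons == 1:
        return "all"
    if season in (0, 1):
        return SEASON_LABELS[season]
    if season in SEASON_LABELS:
        return season
    raise ValueError(f"season must be 'fall' or 'winter', got {season!r}")


def relative_probability_curve(draws: PosteriorDraws, sets: list[ChoiceSet],
                               covariate: str, season,
                               grid_size: int = 100,
                               cri_mass: float = 0.85) -> SelectionCurve:
    """Sweep one covariate against three mean-held alternatives.

    The focal alternative varies the covariate over its observed pooled
    range; with all other covariates at the pooled means, only the focal
    standardized value z differs across alternatives, so per draw of the
    population mean m the relative probability is exp(m z)/(exp(m z) + 3);
    at the covariate mean (z = 0) it is exactly 1/4 for every draw.
    """
    if covariate not in draws.spec.terms:
        raise ValueError(f"covariate {covariate!r} is not in the fitted model")
    label = _season_index(draws, season)
    vals = np.array([a.value(covariate)
                     for cs in sets for a in cs.alternatives])
    grid = np.linspace(vals.min(), vals.max(), grid_size)
    z = draws.params.transform(covariate, grid)
    mu = draws.flat(f"mu[{covariate},{label}]")

    def curve(coef):
        return 1.0 / (1.0 + 3.0 * np.exp(-np.multiply.outer(coef, z)))

    P = curve(mu)  # (draws, grid)
    lo_q, hi_q = 100 * (1 - cri_mass) / 2, 100 * (1 + cri_mass) / 2
    lo, hi = np.percentile(P, [lo_q, hi_q], axis=0)
    coef_lo, coef_hi = np.percentile(mu, [7.5, 92.5])
    return SelectionCurve(covariate, label, grid, z, P.mean(axis=0), lo, hi,
                          curve(coef_lo), curve(coef_hi))
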