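"""Likelihood, posterior, sampler, and diagnostics for the choice model."""

import numpy as np
import pytest
from scipy.stats import halfnorm, norm

from coveychoice.data import assemble_choice_sets, standardize_covariates
from coveychoice.model import (McmcConfig, ModelSpec, PosteriorDraws,
                               build_design, choice_set_loglik, gelman_rubin,
                               log_posterior, sample_posterior,
                               summarize_posterior)
from conftest import make_choice_rows

LOG_QUARTER = np.log(0.25)


def tiny_sets(n_sets=3, n_coveys=2, seed=0, **kwargs):
    return assemble_choice_sets(
        make_choice_rows(n_sets=n_sets, n_coveys=n_coveys, seed=seed, **kwargs))


class TestChoiceSetLoglik:
    def test_zero_coefficients_give_uniform_probability(self, small_sets):
        spec = ModelSpec(("GS", "VO"))
        for cs in small_sets[:5]:
            ll = choice_set_loglik(cs, {"GS": 0.0, "VO": 0.0}, spec)
            assert ll == pytest.approx(LOG_QUARTER, abs=1e-12)

    def test_closed_form_log_three_over_six(self):
        # utilities (ln 3, 0, 0, 0) with the first alternative used:
        # P = 3 / (3 + 1 + 1 + 1), log = -0.6931472
        rows = make_choice_rows(n_sets=1, seed=1)
        rows["TD"] = [np.log(3), 0, 0, 0]
        rows["used"] = [True, False, False, False]
        cs = assemble_choice_sets(rows)[0]
        ll = choice_set_loglik(cs, {"TD": 1.0}, ModelSpec(("TD",)))
        assert ll == pytest.approx(-0.6931472, abs=1e-7)

    def test_softmax_value_e_over_e_plus_three(self):
        # standardized contrast (1, 0, 0, 0) with beta = 1: e/(e+3)
        rows = make_choice_rows(n_sets=1, seed=1)
        rows["TD"] = [1.0, 0, 0, 0]
        rows["used"] = [True, False, False, False]
        cs = assemble_choice_sets(rows)[0]
        ll = choice_set_loglik(cs, {"TD": 1.0}, ModelSpec(("TD",)))
        assert np.exp(ll) == pytest.approx(np.e / (np.e + 3), rel=1e-12)

    def test_shift_invariance(self):
        # adding a constant to every alternative's utility leaves the
        # softmax unchanged (set-constant covariates carry no information)
        rows = make_choice_rows(n_sets=1, seed=2)
        cs = assemble_choice_sets(rows)[0]
        spec = ModelSpec(("GS", "TD"))
        beta = {"GS": 0.7, "TD": -1.2}
        ll = choice_set_loglik(cs, beta, spec)
        rows2 = rows.copy()
        rows2["TD"] += 40.0  # shifts every utility by -1.2 * 40
        ll2 = choice_set_loglik(assemble_choice_sets(rows2)[0], beta, spec)
        assert ll2 == pytest.approx(ll, abs=1e-12)

    def test_probabilities_sum_to_one(self, small_sets):
        spec = ModelSpec(("GS", "VO", "SC"))
        std, _ = standardize_covariates(small_sets)
        rng = np.random.default_rng(0)
        for cs in std[:10]:
            beta = dict(zip(spec.terms, rng.standard_normal(3)))
            total = 0.0
            for j in range(4):
                alts = tuple(
                    type(a)(**{**a.__dict__, "used": i == j})
                    for i, a in enumerate(cs.alternatives))
                cs_j = type(cs)(cs.set_id, cs.covey_id, cs.season, alts)
                total += np.exp(choice_set_loglik(cs_j, beta, spec))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_reordering_alternatives_preserves_likelihood(self, small_sets):
        spec = ModelSpec(("VO", "WE"))
        beta = {"VO": 1.1, "WE": -0.4}
        rng = np.random.default_rng(1)
        for cs in small_sets[:8]:
            perm = rng.permutation(4)
            shuffled = type(cs)(cs.set_id, cs.covey_id, cs.season,
                                tuple(cs.alternatives[i] for i in perm))
            assert choice_set_loglik(shuffled, beta, spec) == pytest.approx(
                choice_set_loglik(cs, beta, spec), abs=1e-12)

    def test_missing_coefficient_rejected(self, small_sets):
        with pytest.raises(ValueError, match="missing"):
            choice_set_loglik(small_sets[0], {"GS": 1.0},
                              ModelSpec(("GS", "VO")))


class TestLogPosterior:
    def test_decomposes_into_likelihood_and_priors(self):
        # independent naive evaluation: explicit softmax per set plus
        # scipy log-densities for every prior term
        sets = tiny_sets(n_sets=3, n_coveys=2, seed=3)
        spec = ModelSpec(("GS",))
        mcmc = McmcConfig(n_iterations=10, burn_in=1, thin=1)
        design = build_design(sets, spec)
        rng = np.random.default_rng(0)
        mu = rng.standard_normal((2, 1))
        sigma = np.abs(rng.standard_normal((2, 1))) + 0.3
        beta = rng.standard_normal((design.n_groups, 1))

        expected = (norm.logpdf(mu, 0, mcmc.prior_mu_sd).sum()
                    + halfnorm.logpdf(sigma, scale=mcmc.prior_sigma_sd).sum())
        for g, (covey, season) in enumerate(design.group_labels):
            expected += norm.logpdf(beta[g, 0], mu[season, 0], sigma[season, 0])
        for i, cs in enumerate(sets):
            u = design.X[i, :, 0] * beta[design.group_idx[i], 0]
            p = np.exp(u) / np.exp(u).sum()
            expected += np.log(p[cs.used_index])
        got = log_posterior(mu, sigma, beta, design, spec, mcmc)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_no_data_reduces_to_prior(self):
        spec = ModelSpec(("GS", "VO"))
        mcmc = McmcConfig(n_iterations=10, burn_in=1, thin=1)
        design = build_design([], spec)
        mu = np.ones((2, 2))
        sigma = np.full((2, 2), 2.0)
        beta = np.empty((0, 2))
        expected = (norm.logpdf(mu, 0, mcmc.prior_mu_sd).sum()
                    + halfnorm.logpdf(sigma, scale=mcmc.prior_sigma_sd).sum())
        assert log_posterior(mu, sigma, beta, design, spec, mcmc) == \
            pytest.approx(expected, abs=1e-10)

    def test_nonpositive_sigma_is_rejected_not_nan(self):
        design = build_design([], ModelSpec(("GS",)))
        mcmc = McmcConfig(n_iterations=10, burn_in=1, thin=1)
        val = log_posterior(np.zeros((2, 1)), np.array([[0.0], [1.0]]),
                            np.empty((0, 1)), design, ModelSpec(("GS",)), mcmc)
        assert val == -np.inf


class TestSampler:
    def test_prior_only_posterior_matches_prior(self):
        # no data: the population-mean posterior is its Normal(0, 10) prior
        spec = ModelSpec(("GS",))
        mcmc = McmcConfig(n_chains=4, n_iterations=4000, burn_in=500, thin=1,
                          seed=0)
        draws = sample_posterior([], spec, mcmc)
        for name in ("mu[GS,fall]", "mu[GS,winter]"):
            x = draws.flat(name)
            assert abs(x.mean()) < 0.6
            assert abs(x.std() - 10.0) < 0.6
        sig = draws.flat("sigma[GS,fall]")
        # half-Normal(1) prior mean is sqrt(2/pi)
        assert abs(sig.mean() - np.sqrt(2 / np.pi)) < 0.1

    def test_same_seed_reproduces_draws(self):
        sets = tiny_sets(n_sets=10, seed=4)
        spec = ModelSpec(("GS", "VO"))
        mcmc = McmcConfig(n_chains=2, n_iterations=400, burn_in=100, thin=2,
                          seed=7)
        a = sample_posterior(sets, spec, mcmc)
        b = sample_posterior(sets, spec, mcmc)
        np.testing.assert_array_equal(a.array, b.array)
        assert a.names == b.names

    def test_retained_count_follows_config(self):
        sets = tiny_sets(n_sets=8, seed=5)
        mcmc = McmcConfig(n_chains=2, n_iterations=503, burn_in=100, thin=7,
                          seed=1)
        draws = sample_posterior(sets, ModelSpec(("VO",)), mcmc)
        assert draws.n_draws == (503 - 100) // 7
        assert draws.n_chains == 2

    def test_set_constant_covariate_is_uninformative(self):
        # a covariate identical across the four alternatives of every set
        # contributes nothing: its posterior equals the Normal(0,10) prior
        rows = make_choice_rows(n_sets=60, seed=6, season=0)
        rows["TD"] = np.repeat(np.linspace(10, 200, 60), 4)
        sets = assemble_choice_sets(rows)
        spec = ModelSpec(("TD",), random_coefficients=False, seasonal=False)
        mcmc = McmcConfig(n_chains=4, n_iterations=12000, burn_in=2000,
                          thin=2, seed=3)
        draws = sample_posterior(sets, spec, mcmc)
        x = draws.flat("mu[TD,all]")
        assert abs(x.mean()) < 1.2
        assert abs(x.std() - 10.0) < 1.2

    def test_null_model_cannot_be_sampled(self, small_sets):
        with pytest.raises(ValueError, match="null"):
            sample_posterior(small_sets, ModelSpec(()))


class TestGelmanRubin:
    def test_null_distribution_near_one(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((4, 1000, 3))
        rh = gelman_rubin(arr)
        assert ((rh > 0.99) & (rh < 1.05)).all()

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        arr = np.stack([rng.standard_normal((500, 1)),
                        100 + rng.standard_normal((500, 1))])
        # independent evaluation of the PSRF formula on the same fixture
        n = 500
        W = arr.var(axis=1, ddof=1).mean(axis=0)[0]
        B_over_n = arr.mean(axis=1).var(axis=0, ddof=1)[0]
        expected = np.sqrt((n - 1) / n + B_over_n / W)
        got = gelman_rubin(arr).iloc[0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 10

    def test_identical_chains_give_sqrt_ratio(self):
        x = np.sin(np.arange(200.0))[None, :, None]
        arr = np.repeat(x, 3, axis=0)
        got = gelman_rubin(arr).iloc[0]
        assert got == pytest.approx(np.sqrt(199 / 200), rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(np.zeros((1, 100, 2)))

    def test_agrees_loosely_with_arviz_rank_rhat(self):
        # arviz computes rank-normalized split R-hat; for well-mixed
        # stationary chains both variants sit near 1
        import arviz as az

        rng = np.random.default_rng(2)
        arr = rng.standard_normal((4, 2000, 1))
        ours = gelman_rubin(arr).iloc[0]
        theirs = float(az.rhat(az.convert_to_dataset(arr[..., 0]))["x"])
        assert abs(ours - theirs) < 0.02


class TestSummaries:
    def _draws(self, values):
        arr = np.asarray(values, dtype=float).reshape(1, -1, 1)
        return PosteriorDraws(arr, ["mu[GS,fall]"], ModelSpec(("GS",)),
                              McmcConfig(n_iterations=2, burn_in=1, thin=1),
                              0, None, [], 2)

    def test_all_positive_draws(self):
        s = summarize_posterior(self._draws([0.5, 1.0, 2.0, 3.0]))
        assert s.iloc[0]["prop_pos"] == 1.0
        assert s.iloc[0]["support"] == "+"

    def test_symmetric_draws_center_at_zero(self):
        vals = np.concatenate([np.arange(1, 51), -np.arange(1, 51)])
        s = summarize_posterior(self._draws(vals))
        assert s.iloc[0]["PM"] == pytest.approx(0.0, abs=1e-12)
        assert s.iloc[0]["cri_lo"] == pytest.approx(-s.iloc[0]["cri_hi"])
        assert s.iloc[0]["support"] == "0"

    def test_percentile_rule_on_integer_ladder(self):
        # equal-tailed 85% CRI of 1..1000 under linear-interpolation
        # percentiles; expected values frozen from numpy's rule
        vals = np.arange(1, 1001, dtype=float)
        expected = np.percentile(vals, [7.5, 92.5])
        s = summarize_posterior(self._draws(vals))
        assert s.iloc[0]["cri_lo"] == pytest.approx(expected[0])
        assert s.iloc[0]["cri_hi"] == pytest.approx(expected[1])
        assert (s.iloc[0]["cri_lo"], s.iloc[0]["cri_hi"]) == \
            pytest.approx((75.925, 925.075))
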