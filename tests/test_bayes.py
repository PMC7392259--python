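import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from segstab.bayes import (
    MCMCConfig,
    PriorSpec,
    attach_stability,
    gibbs_sample,
    log_likelihood,
    log_posterior,
    minimally_informative_priors,
    stability_parameter,
    summarize_posterior,
)
from segstab.errors import InputError
from segstab.segmented import fit_genotype_ols
from segstab.trial_data import transform_T

from conftest import vague_prior
from test_segmented_fit import exact_responses, make_index


@pytest.fixture
def index6():
    return make_index(
        {"E1": -1500.0, "E2": -800.0, "E3": -100.0, "E4": 300.0, "E5": 900.0,
         "E6": 1200.0}
    )


@pytest.fixture
def noisy_responses(index6, rng):
    return exact_responses(index6, 8500.0, 1.1, -0.4) + rng.normal(0, 400, 6)


class TestLogLikelihood:
    def test_zero_residuals_unit_variance(self, index6):
        responses = exact_responses(index6, 8500.0, 1.1, -0.4)
        ll = log_likelihood(8500.0, 1.1, -0.4, 1.0, responses, index6)
        assert ll == pytest.approx(-(6 / 2) * math.log(2 * math.pi))

    def test_matches_per_term_density_oracle(self, index6, noisy_responses):
        b = (8400.0, 1.0, -0.3)
        sigma2 = 2.5e5
        ll = log_likelihood(*b, sigma2, noisy_responses, index6)
        expected = 0.0
        for env, y in noisy_responses.items():
            i = index6.index[env]
            mu = b[0] + b[1] * i + b[2] * transform_T(i, index6.i_plus_bar)
            expected += stats.norm.logpdf(y, mu, math.sqrt(sigma2))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_doubling_sigma2_with_zero_residuals(self, index6):
        responses = exact_responses(index6, 8500.0, 1.1, -0.4)
        ll1 = log_likelihood(8500.0, 1.1, -0.4, 1.0, responses, index6)
        ll2 = log_likelihood(8500.0, 1.1, -0.4, 2.0, responses, index6)
        assert ll1 - ll2 == pytest.approx((6 / 2) * math.log(2))

    def test_nonpositive_variance_rejected(self, index6, noisy_responses):
        with pytest.raises(InputError):
            log_likelihood(0, 0, 0, 0.0, noisy_responses, index6)


class TestLogPosterior:
    def test_difference_matches_density_product_oracle(self, index6, noisy_responses):
        prior = PriorSpec(8000.0, 1.0, 0.0, 1e6, 0.25, 0.25, 2.0, 1e5)
        t1 = (8400.0, 1.0, -0.3, 1 / 2.5e5)
        t2 = (8600.0, 1.3, 0.2, 1 / 4.0e5)

        def oracle(t):
            b0, b1, b2, tau = t
            val = log_likelihood(b0, b1, b2, 1 / tau, noisy_responses, index6)
            val += stats.norm.logpdf(b0, prior.mu_beta0, math.sqrt(prior.var_beta0))
            val += stats.norm.logpdf(b1, prior.mu_beta1, math.sqrt(prior.var_beta1))
            val += stats.norm.logpdf(b2, prior.mu_beta2, math.sqrt(prior.var_beta2))
            val += stats.gamma.logpdf(tau, prior.alpha, scale=1 / prior.beta)
            return val

        got = log_posterior(t1, prior, noisy_responses, index6) - log_posterior(
            t2, prior, noisy_responses, index6
        )
        assert got == pytest.approx(oracle(t1) - oracle(t2), rel=1e-10)

    def test_flat_prior_limit_equals_likelihood_difference(self, index6, noisy_responses):
        prior = PriorSpec(0, 0, 0, 1e308, 1e308, 1e308, 1.0, 1.0)
        t1 = (8400.0, 1.0, -0.3, 1 / 2.5e5)
        t2 = (8600.0, 1.3, 0.2, 1 / 2.5e5)
        dpost = log_posterior(t1, prior, noisy_responses, index6) - log_posterior(
            t2, prior, noisy_responses, index6
        )
        dlik = log_likelihood(*t1[:3], 1 / t1[3], noisy_responses, index6) - (
            log_likelihood(*t2[:3], 1 / t2[3], noisy_responses, index6)
        )
        assert dpost == pytest.approx(dlik, abs=1e-10)


def test_minimally_informative_prior_values():
    prior = minimally_informative_priors()
    assert prior.var_beta0 == 100000.0
    assert prior.var_beta1 == 100000.0
    assert prior.var_beta2 == 100000.0
    assert prior.alpha == 0.001
    assert prior.beta == 0.001
    # prior mean of the precision under the rate parameterization
    assert prior.alpha / prior.beta == 1.0


class TestGibbs:
    def test_reproducible_given_seed(self, index6, noisy_responses):
        cfg = MCMCConfig(iterations=2000, burn_in=200, thin=2, seed=99)
        s1 = gibbs_sample(noisy_responses, index6, vague_prior(), cfg)
        s2 = gibbs_sample(noisy_responses, index6, vague_prior(), cfg)
        pd.testing.assert_frame_equal(s1.draws, s2.draws)
        assert s1.n_draws == cfg.n_retained

    def test_prior_dominates_when_variances_vanish(self, index6, noisy_responses):
        prior = PriorSpec(7777.0, 0.5, -0.25, 1e-12, 1e-12, 1e-12, 1e4, 1e4 * 2.5e5)
        cfg = MCMCConfig(iterations=3000, burn_in=500, thin=1, seed=3)
        sample = gibbs_sample(noisy_responses, index6, prior, cfg)
        means = sample.draws[["beta0", "beta1", "beta2"]].mean()
        assert means["beta0"] == pytest.approx(7777.0, abs=1e-4)
        assert means["beta1"] == pytest.approx(0.5, abs=1e-4)
        assert means["beta2"] == pytest.approx(-0.25, abs=1e-4)

    def test_vague_prior_recovers_ols(self, index6, noisy_responses):
        cfg = MCMCConfig(iterations=20000, burn_in=2000, thin=2, seed=5)
        sample = gibbs_sample(noisy_responses, index6, vague_prior(), cfg)
        fit = fit_genotype_ols(noisy_responses, index6)
        for param, target in (("beta0", fit.b0), ("beta1", fit.b1), ("beta2", fit.b2)):
            draws = sample.draws[param].to_numpy()
            mcse = 3 * draws.std(ddof=1) / math.sqrt(len(draws) / 10)
            assert abs(draws.mean() - target) < mcse

    def test_all_unfavorable_rejected(self):
        index = make_index({f"E{j}": -100.0 * (j + 1) for j in range(6)})
        responses = pd.Series(
            np.linspace(7000, 7500, 6), index=index.index.index
        )
        from segstab.errors import EstimabilityError

        with pytest.raises(EstimabilityError):
            gibbs_sample(responses, index, vague_prior(), MCMCConfig(1000, 100, 1))


class TestStabilityParameter:
    def test_exact_cancellation(self):
        assert stability_parameter(np.array([354330.5]), 708661.0, 2)[0] == 0.0

    def test_printed_arithmetic(self):
        assert stability_parameter(np.array([500000.0]), 708661.0, 2)[0] == pytest.approx(145669.5)

    def test_negative_preserved(self):
        out = stability_parameter(np.array([100000.0]), 708661.0, 2)
        assert out[0] == pytest.approx(-254330.5)

    def test_invalid_r(self):
        with pytest.raises(InputError):
            stability_parameter(np.array([1.0]), 1.0, 0)

    def test_interval_width_unchanged_by_shift(self, index6, noisy_responses):
        cfg = MCMCConfig(iterations=3000, burn_in=500, thin=2, seed=8)
        sample = gibbs_sample(noisy_responses, index6, vague_prior(), cfg)
        sample = attach_stability(sample, msr=7e5, r=2)
        summ = summarize_posterior(sample, noisy_responses, index6)
        lo_s2, hi_s2 = summ.interval("sigma2")
        lo_d, hi_d = summ.interval("sigma2_d")
        assert (hi_d - lo_d) == pytest.approx(hi_s2 - lo_s2, rel=1e-12)
        assert summ.mean("sigma2_d") == pytest.approx(summ.mean("sigma2") - 3.5e5)


class TestSummaries:
    def test_constant_draws_collapse(self, index6):
        responses = exact_responses(index6, 8500.0, 1.1, -0.4)
        draws = pd.DataFrame(
            {
                "beta0": 8500.0, "beta1": 1.1, "beta2": -0.4,
                "tau": 1.0, "sigma2": 1.0, "beta12": 0.7,
            },
            index=range(200),
        )
        sample = _sample_from(draws)
        summ = summarize_posterior(sample, responses, index6)
        row = summ.table.loc["beta1"]
        assert row["mean"] == pytest.approx(1.1, rel=1e-12)
        assert row["lower"] == row["upper"] == 1.1
        # posterior-mean coefficients reproduce the data exactly
        assert summ.r_squared == pytest.approx(100.0)

    def test_percentiles_match_sort_oracle(self, index6):
        responses = exact_responses(index6, 8500.0, 1.1, -0.4)
        vals = np.arange(1.0, 1001.0)
        draws = pd.DataFrame(
            {
                "beta0": vals, "beta1": vals, "beta2": vals,
                "tau": vals, "sigma2": vals, "beta12": vals,
            }
        )
        summ = summarize_posterior(_sample_from(draws), responses, index6)
        lo, hi = summ.interval("beta1")
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_too_few_draws_rejected(self, index6):
        responses = exact_responses(index6, 8500.0, 1.1, -0.4)
        draws = pd.DataFrame(
            {c: np.ones(50) for c in ("beta0", "beta1", "beta2", "tau", "sigma2", "beta12")}
        )
        with pytest.raises(InputError):
            summarize_posterior(_sample_from(draws), responses, index6)


def _sample_from(draws):
    from segstab.bayes import PosteriorSample

    return PosteriorSample(
        genotype="G", draws=draws,
        config=MCMCConfig(iterations=len(draws) + 1, burn_in=0, thin=1),
        prior=vague_prior(),
    )
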