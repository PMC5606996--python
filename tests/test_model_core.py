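"""Cumulative-probit likelihood, MLE and Wald inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from ordgene import (
    InvalidParameterError,
    OrdinalPhenotype,
    cumulative_probability,
    fit_cumulative_link,
    negative_log_likelihood,
)
from ordgene.model_core import _category_probabilities, get_link


class TestCumulativeProbability:
    @pytest.mark.parametrize(
        "alphas, beta, x, i, expected",
        [
            ([0.0], 0.0, 3.7, 1, 0.5),                 # Phi(0)
            ([1.0], 1.0, 1.0, 1, 0.5),                 # Phi(1 - 1)
            ([-1.0, 1.0], 0.5, 2.0, 2, 0.5),           # Phi(1 - 1)
            ([-1.0, 1.0], 0.5, 2.0, 1, norm.cdf(-2.0)),  # ~0.02275
        ],
    )
    def test_worked_values(self, alphas, beta, x, i, expected):
        assert cumulative_probability(alphas, beta, x, i) == pytest.approx(
            expected, abs=1e-12
        )

    def test_unordered_alphas_rejected(self):
        with pytest.raises(InvalidParameterError):
            cumulative_probability([1.0, -1.0], 0.5, 0.0, 1)

    def test_monotone_in_level_index(self):
        alphas = [-1.2, -0.3, 0.8, 2.0]
        probs = [cumulative_probability(alphas, 0.7, 0.4, i) for i in range(1, 5)]
        assert np.all(np.diff(probs) >= 0)

    def test_monotone_nonincreasing_in_x_for_positive_beta(self):
        xs = np.linspace(-4, 4, 50)
        p = cumulative_probability([-0.5, 0.5], 1.3, xs, 1)
        assert np.all(np.diff(p) <= 0)

    @given(
        a1=st.floats(-3, 3),
        gap=st.floats(0.01, 3),
        beta=st.floats(-3, 3),
        x=st.floats(-5, 5),
    )
    @settings(deadline=None, max_examples=60)
    def test_category_probabilities_normalize(self, a1, gap, beta, x):
        alphas = np.array([a1, a1 + gap])
        probs = _category_probabilities(alphas, beta, np.array([x]), get_link("probit"))
        assert probs.shape == (1, 3)
        assert np.all(probs >= -1e-15)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestNegativeLogLikelihood:
    def test_single_sample_at_origin(self):
        # one sample, k=1, alpha=0, beta=0, lowest category: -log Phi(0)
        assert negative_log_likelihood([0.0, 0.0], [1.3], [0]) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_hand_summed_gaussian_cdf_toy(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        alpha, beta = 0.2, 0.9
        # independent sum of log Gaussian-CDF terms
        expected = -(
            np.log(norm.cdf(alpha - beta * -1.0))
            + np.log(norm.cdf(alpha - beta * 0.0))
            + np.log(1 - norm.cdf(alpha - beta * 1.0))
            + np.log(1 - norm.cdf(alpha - beta * 2.0))
        )
        got = negative_log_likelihood([alpha, beta], x, y)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_probability_observation_gives_inf(self):
        # Phi(-50) underflows to exactly 0: observing the lowest category there
        assert negative_log_likelihood([0.0, 1.0], [50.0], [0]) == np.inf

    def test_k1_is_binary_probit_nll(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        alpha, beta = 0.3, -0.8
        # binary probit with P(Y=1|x) = Phi(beta*x - alpha)
        eta = beta * x - alpha
        expected = -np.sum(np.where(y == 1, norm.logcdf(eta), norm.logcdf(-eta)))
        assert negative_log_likelihood([alpha, beta], x, y) == pytest.approx(
            expected, rel=1e-12
        )


class TestFit:
    def test_symmetric_balanced_data_zero_slope(self):
        # each x value carries identical grade counts -> slope must vanish
        x = np.repeat([-1.0, 1.0], 3)
        y = np.array([0, 1, 2, 0, 1, 2])
        fit = fit_cumulative_link(x, y)
        assert abs(fit.beta) < 1e-6

    def test_binary_reduction_matches_independent_probit(self):
        from statsmodels.discrete.discrete_model import Probit

        rng = np.random.default_rng(11)
        x = rng.normal(size=120)
        latent = 0.8 * x + rng.normal(size=120)
        y = (latent > 0.2).astype(int)
        fit = fit_cumulative_link(x, y, tol=1e-10)
        sm = Probit(y, np.column_stack([np.ones_like(x), x])).fit(disp=False, tol=1e-12)
        # P(Y=1|x) = Phi(beta*x - alpha): const = -alpha, slope = beta
        assert fit.beta == pytest.approx(sm.params[1], abs=1e-6)
        assert -fit.alphas[0] == pytest.approx(sm.params[0], abs=1e-6)

    def test_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        latent = 1.2 * x + rng.normal(size=200)
        y = np.digitize(latent, [-0.8, 0.5, 1.5])
        fit = fit_cumulative_link(x, y)
        sm = OrderedModel(y, x[:, None], distr="probit").fit(method="bfgs", disp=False)
        thresholds = sm.model.transform_threshold_params(sm.params)[1:-1]
        assert fit.loglik >= sm.llf - 1e-7  # our MLE is at least as good
        assert fit.beta == pytest.approx(sm.params[0], abs=1e-4)
        assert fit.alphas == pytest.approx(np.asarray(thresholds), abs=1e-4)
        assert fit.se_beta == pytest.approx(sm.bse[0], rel=1e-3)

    def test_estimate_close_to_truth_large_n(self):
        from ordgene import simulate_ordinal_cohort

        expr, pheno, truth = simulate_ordinal_cohort(
            1, n_samples=2000, pag_fraction=1.0, beta_range=(1.5, 1.5), seed=99
        )
        fit = fit_cumulative_link(expr.iloc[0].to_numpy(), pheno.grades)
        assert abs(fit.beta - truth.beta[0]) < 3 * fit.se_beta
        assert fit.converged
        assert np.isfinite(fit.loglik)

    def test_alphas_strictly_increasing_and_p_in_unit_interval(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        y = rng.integers(0, 4, size=80)
        fit = fit_cumulative_link(x, y)
        assert np.all(np.diff(fit.alphas) > 0)
        assert np.all((fit.p_values >= 0) & (fit.p_values <= 1))
        assert len(fit.alphas) == 3
        assert fit.n_obs == 80

    def test_constant_covariate_refused(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cumulative_link(np.ones(10), np.array([0, 1] * 5))

    def test_single_level_refused(self):
        with pytest.raises(ValueError, match="levels"):
            fit_cumulative_link(np.arange(6.0), np.zeros(6, dtype=int))

    def test_separation_flagged_with_conservative_p(self):
        x = np.arange(10.0)
        y = (x > 4).astype(int)
        fit = fit_cumulative_link(x, y)
        assert fit.separated
        assert np.all(fit.p_values == 1.0)

    def test_logit_link_supported(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=150)
        y = np.digitize(1.0 * x + rng.logistic(size=150), [-1.0, 1.0])
        fit = fit_cumulative_link(x, y, link="logit")
        assert fit.converged
        assert fit.beta > 0


class TestOrdinalPhenotype:
    def test_validates_levels(self):
        with pytest.raises(ValueError):
            OrdinalPhenotype(["a", "b"], np.array([0, 0]))  # single level
        with pytest.raises(ValueError):
            OrdinalPhenotype(["a"], np.array([0, 1]))  # length mismatch
        with pytest.raises(ValueError):
            OrdinalPhenotype(["a", "b"], np.array([0, 3]), ["lo", "hi"])  # range

    def test_counts(self):
        ph = OrdinalPhenotype(list("abcd"), np.array([0, 1, 1, 2]))
        assert ph.k == 2
        assert ph.level_counts().tolist() == [1, 2, 1]
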