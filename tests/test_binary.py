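"""Logistic DGP: linear predictors, potential outcomes, MLE fit, c-statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dgpbisect as dg
from dgpbisect.superpop import SuperPopulation

OUTCOME_COEFS = dg.OUTCOME_LOG_ODDS_RATIOS


def tiny_population(values, roles):
    return SuperPopulation(values=np.asarray(values, dtype=float), column_roles=roles)


class TestLinearPredictor:
    def test_zero_covariates_leave_only_intercept(self):
        pop = tiny_population(np.zeros((4, 10)), ("continuous",) * 5 + ("binary",) * 5)
        spec = dg.LogisticModelSpec(intercept=-4.368896, coefficients=OUTCOME_COEFS)
        lp = dg.linear_predictor(pop, spec)
        assert np.all(lp == -4.368896)

    def test_zero_scale_annihilates_covariate_sum(self):
        rng = np.random.default_rng(0)
        pop = tiny_population(rng.standard_normal((6, 10)), ("continuous",) * 10)
        spec = dg.LogisticModelSpec(intercept=1.5, coefficients=OUTCOME_COEFS, treatment_log_or=0.7, scale=0.0)
        z = np.array([0, 1, 0, 1, 1, 0])
        lp = dg.linear_predictor(pop, spec, treatment=z)
        assert np.allclose(lp, 1.5 + 0.7 * z)

    def test_all_ones_subject_sums_the_log_odds_ratios(self):
        pop = tiny_population(np.ones((1, 10)), ("continuous",) * 5 + ("binary",) * 5)
        spec = dg.LogisticModelSpec(intercept=0.0, coefficients=OUTCOME_COEFS)
        expected = 2 * sum(math.log(o) for o in (1.25, 1.5, 1.75, 2.0, 2.5))
        assert dg.linear_predictor(pop, spec)[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(5.59533, abs=1e-5)

    def test_dimension_mismatch_rejected(self):
        pop = tiny_population(np.zeros((3, 2)), ("continuous", "continuous"))
        with pytest.raises(dg.SpecificationError):
            dg.linear_predictor(pop, dg.LogisticModelSpec(0.0, OUTCOME_COEFS))

    def test_scale_preserves_coefficient_ratios(self):
        """Scaling multiplies every log-odds ratio but leaves their ratios fixed."""
        rng = np.random.default_rng(1)
        pop = tiny_population(rng.standard_normal((8, 10)), ("continuous",) * 10)
        base = dg.LogisticModelSpec(intercept=-1.0, coefficients=OUTCOME_COEFS, scale=1.0)
        scaled = dg.LogisticModelSpec(intercept=-1.0, coefficients=OUTCOME_COEFS, scale=2.5)
        assert np.allclose(
            dg.linear_predictor(pop, scaled) + 1.0, 2.5 * (dg.linear_predictor(pop, base) + 1.0)
        )


class TestOutcomeSimulation:
    def test_extreme_linear_predictors_are_degenerate(self):
        rng = np.random.default_rng(0)
        assert dg.simulate_binary_outcomes(np.full(100, -700.0), rng).sum() == 0
        assert dg.simulate_binary_outcomes(np.full(100, 700.0), rng).sum() == 100

    def test_empirical_prevalence_examples(self):
        assert dg.empirical_prevalence(np.zeros(10, dtype=int)) == 0.0
        assert dg.empirical_prevalence(np.array([1, 0, 1, 0])) == 0.5
        with pytest.raises(dg.SpecificationError):
            dg.empirical_prevalence(np.array([]))


class TestTreatmentAssignment:
    def test_null_selection_model_gives_half_prevalence(self, population_100k):
        model = dg.LogisticModelSpec(intercept=0.0, coefficients=np.zeros(10))
        z = dg.simulate_treatment(population_100k, model, np.random.default_rng(4))
        # 4 binomial SEs around 0.5 at N=1e5
        assert abs(z.mean() - 0.5) < 4 * 0.5 / np.sqrt(population_100k.n)

    def test_deeply_negative_intercept_assigns_nobody(self, population_100k):
        model = dg.LogisticModelSpec(intercept=-700.0, coefficients=np.zeros(10))
        z = dg.simulate_treatment(population_100k, model, np.random.default_rng(4))
        assert z.sum() == 0

    def test_treatment_model_must_not_contain_treatment_term(self, population_100k):
        model = dg.LogisticModelSpec(intercept=0.0, coefficients=np.zeros(10), treatment_log_or=0.3)
        with pytest.raises(dg.SpecificationError):
            dg.simulate_treatment(population_100k, model, np.random.default_rng(4))


class TestPotentialOutcomes:
    def spec(self, gamma):
        return dg.LogisticModelSpec(intercept=-4.367676, coefficients=OUTCOME_COEFS, treatment_log_or=gamma)

    def test_null_effect_with_shared_uniforms_gives_identical_arms(self, population_100k):
        y0, y1 = dg.potential_binary_outcomes(
            population_100k, self.spec(0.0), np.random.default_rng(5), shared_uniforms=True
        )
        assert np.array_equal(y0, y1)

    def test_null_effect_marginals_within_monte_carlo_error(self, population_100k):
        y0, y1 = dg.potential_binary_outcomes(population_100k, self.spec(0.0), np.random.default_rng(6))
        m0, m1 = y0.mean(), y1.mean()
        n = population_100k.n
        se_log_rr = np.sqrt((1 - m0) / (n * m0) + (1 - m1) / (n * m1))
        assert abs(np.log(dg.marginal_relative_risk(y0, y1))) < 4 * se_log_rr
        se_rd = np.sqrt(m0 * (1 - m0) / n + m1 * (1 - m1) / n)
        assert abs(dg.marginal_risk_difference(y0, y1)) < 4 * se_rd

    def test_infinitely_protective_treatment_zeroes_the_treated_arm(self, population_100k):
        y0, y1 = dg.potential_binary_outcomes(population_100k, self.spec(-700.0), np.random.default_rng(7))
        assert y1.sum() == 0
        assert dg.marginal_relative_risk(y0, y1) == 0.0

    def test_relative_risk_denominator_guard(self):
        with pytest.raises(dg.DegenerateEstimandError):
            dg.marginal_relative_risk(np.zeros(10, dtype=int), np.ones(10, dtype=int))

    def test_risk_difference_on_constructed_vectors(self):
        y0 = np.zeros(100, dtype=int)
        y0[:10] = 1  # mean 0.10
        y1 = np.zeros(100, dtype=int)
        y1[:8] = 1  # mean 0.08
        assert dg.marginal_risk_difference(y0, y1) == pytest.approx(-0.02, abs=1e-15)

    def test_marginal_effects_increase_with_treatment_log_odds_ratio(self, population_100k):
        rng = np.random.default_rng(8)
        rrs, rds = [], []
        for gamma in (-1.0, -0.5, 0.0, 0.5):
            y0, y1 = dg.potential_binary_outcomes(population_100k, self.spec(gamma), rng)
            rrs.append(dg.marginal_relative_risk(y0, y1))
            rds.append(dg.marginal_risk_difference(y0, y1))
        assert rrs == sorted(rrs)
        assert rds == sorted(rds)


class TestLogisticMLE:
    @staticmethod
    def two_by_two(a, b, c, d):
        """a/b = events/non-events among exposed, c/d among unexposed."""
        x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        pop = tiny_population(x[:, None], ("binary",))
        return pop, y

    def test_balanced_table_gives_zero_slope(self):
        pop, y = self.two_by_two(10, 10, 10, 10)
        fit = dg.fit_logistic_mle(pop, y)
        assert fit.params[1] == pytest.approx(0.0, abs=1e-8)

    def test_saturated_table_matches_log_odds_ratio(self):
        pop, y = self.two_by_two(20, 10, 10, 20)
        fit = dg.fit_logistic_mle(pop, y)
        assert fit.params[1] == pytest.approx(math.log(4.0), abs=1e-7)

    def test_single_class_outcomes_rejected(self):
        pop = tiny_population(np.random.default_rng(0).standard_normal((20, 1)), ("continuous",))
        with pytest.raises(dg.FitError):
            dg.fit_logistic_mle(pop, np.ones(20))

    def test_matches_statsmodels_on_moderate_sample(self, population_100k):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        idx = rng.choice(population_100k.n, 2000, replace=False)
        pop = SuperPopulation(population_100k.values[idx], population_100k.column_roles)
        spec = dg.LogisticModelSpec(intercept=-1.0, coefficients=OUTCOME_COEFS)
        y = dg.simulate_binary_outcomes(dg.linear_predictor(pop, spec), rng)
        fit = dg.fit_logistic_mle(pop, y)
        reference = sm.Logit(y, sm.add_constant(pop.values)).fit(disp=0)
        assert np.allclose(fit.params, reference.params, atol=1e-6)
        assert np.allclose(fit.bse, reference.bse, rtol=1e-4)


class TestCStatistic:
    def test_perfect_separation_and_all_ties(self):
        y = np.array([1, 1, 0, 0])
        assert dg.c_statistic(np.array([4.0, 3.0, 2.0, 1.0]), y) == 1.0
        assert dg.c_statistic(np.zeros(4), y) == 0.5

    def test_enumerated_pairs_example(self):
        # cases {3, 1}, controls {2, 0}: 3 of 4 pairs concordant
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        y = np.array([1, 1, 0, 0])
        assert dg.c_statistic(scores, y) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(dg.DegenerateEstimandError):
            dg.c_statistic(np.arange(4.0), np.ones(4))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        scores = rng.standard_normal(500)
        y = (rng.random(500) < 0.3).astype(int)
        base = dg.c_statistic(scores, y)
        assert dg.c_statistic(3.0 * scores + 2.0, y) == base
        assert dg.c_statistic(np.exp(scores), y) == base

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        n=st.integers(4, 80),
        seed=st.integers(0, 10_000),
        tie_heavy=st.booleans(),
    )
    def test_rank_sum_matches_pairwise_enumeration(self, n, seed, tie_heavy):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, n).astype(float) if tie_heavy else rng.standard_normal(n)
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, rng.integers(1, n), replace=False)] = 1
        if y.min() == y.max():
            y[0] = 1 - y[0]
        cases, controls = scores[y == 1], scores[y == 0]
        wins = (cases[:, None] > controls[None, :]).sum() + 0.5 * (cases[:, None] == controls[None, :]).sum()
        brute = wins / (len(cases) * len(controls))
        assert dg.c_statistic(scores, y) == pytest.approx(brute, abs=1e-12)
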