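import numpy as np
import pandas as pd
import pytest

from csearch.data_model import EVENT, TIME, TREATMENT, Cohort
from csearch.propensity import (
    PropensityFitError,
    fit_propensity,
    ipw_gene_posterior,
    propensity_match,
    standardized_mean_differences,
)
from csearch.synthetic_data import SimulationScenario, simulate_cohort
from csearch.win_probability import BetaPosterior, WinPosterior
from conftest import build_cohort


def _assignment_cohort(n=2000, beta=2.0, seed=0):
    """Treatment assigned by a known logistic model on one covariate."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    t = rng.binomial(1, 1 / (1 + np.exp(-beta * x)))
    clin = pd.DataFrame(
        {
            "x": x,
            TREATMENT: t,
            TIME: rng.exponential(10, n),
            EVENT: rng.binomial(1, 0.7, n),
        },
        index=pd.Index([f"s{k}" for k in range(n)], name="sample_id"),
    )
    return Cohort(clin)


class TestFitPropensity:
    def test_null_model_predicts_half(self):
        cohort = _assignment_cohort(n=2000, beta=0.0, seed=1)
        model = fit_propensity(cohort, "clinical")
        e = model.predict(cohort)
        assert (np.abs(e - 0.5) < 0.05).all()

    def test_coefficient_recovery_within_three_se(self):
        cohort = _assignment_cohort(n=2000, beta=2.0, seed=2)
        model = fit_propensity(cohort, "clinical", ridge=1e-4)
        beta_hat = model.coefficients["x"]
        se = 1 / np.sqrt(cohort.n * 0.15)  # crude logistic information bound
        assert abs(beta_hat - 2.0) < 3 * se

    def test_constant_covariate_dropped_intercept_only(self, caplog):
        cohort = build_cohort(times=[1, 2, 3, 4], events=[1, 1, 1, 1],
                              treatment=[1, 0, 1, 0],
                              age=[50, 50, 50, 50], sex=[1, 1, 1, 1])
        with caplog.at_level("WARNING"):
            model = fit_propensity(cohort, "clinical")
        assert "constant" in caplog.text
        assert (model.coefficients[["age", "sex"]] == 0).all()
        np.testing.assert_allclose(model.predict(cohort), 0.5, atol=1e-9)

    def test_single_arm_rejected(self):
        cohort = build_cohort(times=[1, 2], events=[1, 1], treatment=[1, 1])
        with pytest.raises(PropensityFitError, match="arms"):
            fit_propensity(cohort, "clinical")

    def test_predictions_respect_clip_bounds(self):
        cohort = _assignment_cohort(n=500, beta=5.0, seed=3)
        model = fit_propensity(cohort, "clinical", ridge=1e-6)
        e = model.predict(cohort)
        assert e.min() >= 0.05 and e.max() <= 0.95
        assert model.n_clipped > 0


class TestIpwGenePosterior:
    def _wins(self, pws):
        return [
            WinPosterior(f"i{k}", BetaPosterior(10 * pw, 10 * (1 - pw)), 1.0)
            for k, pw in enumerate(pws)
        ]

    def test_hand_arithmetic_fixture(self):
        # e(V)=e(G)=0.5, Pw=(0.8, 0.6): Beta(1 + 1.4/0.25, 1 + 0.6/0.25)
        wins = self._wins([0.8, 0.6])
        post = ipw_gene_posterior(wins, np.full(2, 0.5), np.full(2, 0.5),
                                  BetaPosterior(1, 1))
        assert post.alpha == pytest.approx(6.6)
        assert post.beta == pytest.approx(3.4)

    def test_stabilized_total_two_mean_preserved(self):
        wins = self._wins([0.8, 0.6])
        post = ipw_gene_posterior(wins, np.full(2, 0.5), np.full(2, 0.5),
                                  BetaPosterior(1, 1), stabilized=True)
        assert post.total == pytest.approx(4.0)  # prior 2 + one per individual
        assert post.alpha == pytest.approx(2.4)
        assert post.beta == pytest.approx(1.6)

    def test_stabilized_half_propensities_equal_unweighted(self):
        pws = [0.9, 0.3, 0.55]
        wins = self._wins(pws)
        post = ipw_gene_posterior(wins, np.full(3, 0.5), np.full(3, 0.5),
                                  BetaPosterior(1, 1), stabilized=True)
        assert post.alpha == pytest.approx(1 + sum(pws))
        assert post.beta == pytest.approx(1 + 3 - sum(pws))

    def test_empty_carrier_list_returns_prior(self):
        prior = BetaPosterior(2, 3)
        assert ipw_gene_posterior([], np.array([]), np.array([]), prior) == prior

    def test_unclipped_propensity_rejected(self):
        wins = self._wins([0.5])
        with pytest.raises(ValueError, match="clip"):
            ipw_gene_posterior(wins, np.array([1.0]), np.array([0.5]),
                               BetaPosterior(1, 1))


class TestPropensityMatch:
    def test_greedy_rule_on_two_pairs(self):
        # treated logits ~ (0, 5); untreated ~ (0.1, 5.1): nearest-neighbor pairs
        cohort = build_cohort(
            times=[1, 2, 3, 4], events=[1, 1, 1, 1], treatment=[1, 1, 0, 0],
            age=[0.0, 5.0, 0.1, 5.1], sex=[0, 0, 0, 0],
        )
        model = fit_propensity(cohort, "clinical")
        matched, result = propensity_match(cohort, model, caliper_sd=100.0)
        assert result.pairs == (("P01", "P03"), ("P02", "P04"))
        assert matched.n == 4

    def test_identical_propensities_pair_up_to_min_arm(self):
        cohort = build_cohort(
            times=list(range(1, 8)), events=[1] * 7, treatment=[1, 1, 1, 0, 0, 0, 0],
            age=[50] * 7, sex=[0] * 7,
        )
        model = fit_propensity(cohort, "clinical")
        matched, result = propensity_match(cohort, model)
        assert len(result.pairs) == 3

    def test_out_of_caliper_treated_excluded(self):
        cohort = build_cohort(
            times=[1, 2, 3, 4], events=[1] * 4, treatment=[1, 1, 0, 0],
            age=[0.0, 50.0, 0.1, 0.2], sex=[0] * 4,
        )
        model = fit_propensity(cohort, "clinical", ridge=1e-4)
        matched, result = propensity_match(cohort, model, caliper_sd=0.2)
        assert "P02" in result.unmatched_treated

    def test_matching_balances_confounded_covariates(self):
        # age drives assignment; matching on a correct model restores balance
        rng = np.random.default_rng(5)
        n = 2000
        age = rng.normal(60, 10, n)
        t = rng.binomial(1, 1 / (1 + np.exp(-(age - 60) / 5)))
        cohort = build_cohort(
            times=rng.exponential(10, n), events=rng.binomial(1, 0.7, n),
            treatment=t, age=age, sex=rng.binomial(1, 0.5, n),
        )
        assert standardized_mean_differences(cohort)["age"] > 0.3
        model = fit_propensity(cohort, "clinical")
        matched, _ = propensity_match(cohort, model)
        assert (standardized_mean_differences(matched) < 0.1).all()
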