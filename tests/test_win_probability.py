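import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csearch.basal_model import fit_basal
from csearch.data_model import SurvivalOutcome
from csearch.similarity import SimilarityWeights
from csearch.win_probability import (
    UNIFORM_PRIOR,
    BetaPosterior,
    all_win_posteriors,
    compare_pair,
    individual_win_posterior,
    score_matrix,
)
from conftest import build_cohort


class TestBetaPosterior:
    def test_mean_and_update(self):
        post = BetaPosterior(1, 1).updated(1.0, 0.0)
        assert post.mean == pytest.approx(2 / 3)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            BetaPosterior(0.0, 1.0)

    def test_credible_interval_brackets_mean(self):
        lo, hi = BetaPosterior(5, 3).credible_interval()
        assert lo < 5 / 8 < hi


class TestComparePair:
    # all eight censoring/order configurations, checked against the
    # comparability definition: the smaller observed time must be an event
    CASES = [
        ((10, 1), (5, 1), 1.0),     # both events, i later -> win
        ((5, 1), (10, 1), 0.0),     # both events, i earlier -> loss
        ((7, 1), (7, 1), 0.5),      # tied event times
        ((10, 0), (5, 1), 1.0),     # i censored after j's death: i outlived j
        ((5, 1), (10, 0), 0.0),     # symmetric
        ((3, 0), (5, 1), None),     # i censored before j's death: unknowable
        ((5, 1), (3, 0), None),     # symmetric
        ((4, 0), (9, 0), None),     # both censored
    ]

    @pytest.mark.parametrize("yi,yj,expected", CASES)
    def test_enumerated_cases(self, yi, yj, expected):
        s = compare_pair(SurvivalOutcome(*yi), SurvivalOutcome(*yj))
        assert s == expected

    def test_censored_at_death_time_counts(self):
        # censoring exactly at j's death time still proves survival past it
        assert compare_pair(SurvivalOutcome(5, 0), SurvivalOutcome(5, 1)) == 1.0

    def test_score_matrix_matches_scalar(self):
        times = [10, 5, 7, 3, 9]
        events = [1, 1, 0, 1, 0]
        outcomes = [SurvivalOutcome(t, e) for t, e in zip(times, events)]
        S, comp = score_matrix(times, events, times, events)
        for i, j in itertools.product(range(5), repeat=2):
            s = compare_pair(outcomes[i], outcomes[j])
            if s is None:
                assert not comp[i, j]
            else:
                assert comp[i, j] and S[i, j] == s


def _individual(id_, time, event, treated=1):
    from csearch.data_model import Individual

    return Individual(id_, np.zeros(1), np.zeros(1, dtype=np.int8), treated,
                      SurvivalOutcome(time, event))


def _weights(ids, values):
    return SimilarityWeights("i", tuple(ids), np.asarray(values, float), 1.0)


class TestIndividualWinPosterior:
    def test_single_winning_pair(self):
        i = _individual("i", 10, 1)
        pool = [_individual("j0", 5, 1, 0)]
        w = _weights(["j0"], [1.0])
        post = individual_win_posterior(i, pool, w, w)
        assert (post.posterior.alpha, post.posterior.beta) == (2.0, 1.0)
        assert post.pw == pytest.approx(2 / 3)

    def test_boltzmann_weighted_hand_arithmetic(self):
        # weights (0.73106, 0.26894) with s = (1, 0): Beta(1.73106, 1.26894)
        i = _individual("i", 10, 1)
        pool = [_individual("j0", 5, 1, 0), _individual("j1", 20, 1, 0)]
        w = _weights(["j0", "j1"], [0.7310585786, 0.2689414214])
        uniform = _weights(["j0", "j1"], [0.5, 0.5])
        post = individual_win_posterior(i, pool, w, uniform)
        assert post.posterior.alpha == pytest.approx(1.7310585786, abs=1e-9)
        assert post.posterior.beta == pytest.approx(1.2689414214, abs=1e-9)
        assert post.pw == pytest.approx(0.57702, abs=1e-4)

    def test_all_incomparable_returns_flagged_prior(self):
        i = _individual("i", 3, 0)
        pool = [_individual("j0", 5, 1, 0), _individual("j1", 9, 0, 0)]
        w = _weights(["j0", "j1"], [0.5, 0.5])
        post = individual_win_posterior(i, pool, w, w)
        assert post.no_evidence
        assert post.posterior == UNIFORM_PRIOR

    def test_incomparable_weight_redistributed(self):
        # one comparable (s=1, w=0.5) + one incomparable (w=0.5):
        # renormalized over comparable pairs -> full unit weight on the win
        i = _individual("i", 10, 1)
        pool = [_individual("j0", 5, 1, 0), _individual("j1", 3, 0, 0)]
        w = _weights(["j0", "j1"], [0.5, 0.5])
        post = individual_win_posterior(i, pool, w, w)
        assert post.posterior.alpha == pytest.approx(2.0)
        assert post.posterior.beta == pytest.approx(1.0)

    def test_half_rule_counts_incomparables_as_half(self):
        i = _individual("i", 10, 1)
        pool = [_individual("j0", 5, 1, 0), _individual("j1", 3, 0, 0)]
        w = _weights(["j0", "j1"], [0.5, 0.5])
        post = individual_win_posterior(i, pool, w, w, incomparable="half")
        assert post.posterior.alpha == pytest.approx(1.75)
        assert post.posterior.beta == pytest.approx(1.25)

    def test_misaligned_weights_rejected(self):
        i = _individual("i", 10, 1)
        pool = [_individual("j0", 5, 1, 0)]
        w = _weights(["zz"], [1.0])
        with pytest.raises(ValueError, match="aligned"):
            individual_win_posterior(i, pool, w, w)


def _brute_force_wmw(cohort, i_idx, pool_idx):
    """Unweighted Mann-Whitney win fraction over comparable pairs."""
    t, e = cohort.time, cohort.event
    outcomes = [SurvivalOutcome(float(t[k]), int(e[k])) for k in range(cohort.n)]
    scores = [
        s for j in pool_idx
        if (s := compare_pair(outcomes[i_idx], outcomes[j])) is not None
    ]
    return float(np.mean(scores)) if scores else None


class TestAllWinPosteriors:
    @pytest.fixture()
    def fitted(self, toy_cohort):
        bv = fit_basal(toy_cohort, "clinical")
        bg = fit_basal(toy_cohort, "genetic")
        return bv, bg

    def test_dominant_treated_all_above_half(self):
        cohort = build_cohort(
            times=[50, 60, 70, 5, 6, 7], events=[1] * 6,
            treatment=[1, 1, 1, 0, 0, 0],
            genes={"gA": [1, 0, 1, 0, 1, 0]},
        )
        bv = fit_basal(cohort, "clinical")
        bg = fit_basal(cohort, "genetic")
        for post in all_win_posteriors(cohort, bv, bg):
            assert post.pw > 0.5

    def test_uniform_weights_reduce_to_wmw_oracle(self, toy_cohort, fitted):
        bv, bg = fitted
        posts = all_win_posteriors(toy_cohort, bv, bg, k_tau=1e9)
        t = toy_cohort.treatment
        pool_idx = np.where(t == 0)[0]
        ids = list(toy_cohort.ids)
        for post in posts:
            i_idx = ids.index(post.i_id)
            sbar = _brute_force_wmw(toy_cohort, i_idx, pool_idx)
            expected = (1.0 + sbar) / 3.0  # Beta(1+s, 1+(1-s)) mean
            assert post.pw == pytest.approx(expected, abs=1e-9)

    def test_direction_swap_reflects_around_half(self, toy_cohort, fitted):
        # no censoring, uniform weights: mean Pw(treated) + mean Pw(untreated) = 1
        bv, bg = fitted
        fwd = all_win_posteriors(toy_cohort, bv, bg, k_tau=1e9)
        rev = all_win_posteriors(toy_cohort, bv, bg, k_tau=1e9,
                                 direction="untreated_vs_treated")
        m_f = np.mean([p.pw for p in fwd])
        m_r = np.mean([p.pw for p in rev])
        assert m_f + m_r == pytest.approx(1.0, abs=1e-9)

    def test_pseudo_count_conservation(self, small_sim):
        bv = fit_basal(small_sim.cohort, "clinical")
        bg = fit_basal(small_sim.cohort, "genetic")
        for post in all_win_posteriors(small_sim.cohort, bv, bg):
            added = post.posterior.total - UNIFORM_PRIOR.total
            if post.no_evidence:
                assert added == 0.0
            else:
                assert added == pytest.approx(1.0, abs=1e-9)

    def test_pool_permutation_invariance(self, toy_cohort, fitted):
        bv, bg = fitted
        from csearch.data_model import Cohort

        base = {p.i_id: p.pw for p in all_win_posteriors(toy_cohort, bv, bg)}
        rng = np.random.default_rng(0)
        perm = rng.permutation(toy_cohort.n)
        shuffled = Cohort(toy_cohort.clinical.iloc[perm], toy_cohort.genes.iloc[perm])
        again = {p.i_id: p.pw for p in all_win_posteriors(shuffled, bv, bg)}
        for k, v in base.items():
            assert again[k] == pytest.approx(v, abs=1e-12)

    def test_single_arm_cohort_rejected(self):
        cohort = build_cohort(times=[1, 2, 3], events=[1, 1, 1], treatment=[1, 1, 1])
        with pytest.raises(ValueError, match="both treatment arms"):
            all_win_posteriors(cohort, None, None)
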