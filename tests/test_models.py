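"""Choice models: reward recoding, value updates, likelihoods, fitting, AIC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matchingpennies.agents import FixAgent, play_block
from matchingpennies.game import (
    Choice,
    DEFAULT_PAYOFF,
    OpponentType,
    PayoffMatrix,
    TrialRecord,
    resolve_trial,
)
from matchingpennies.models import (
    FitConfig,
    FitResult,
    LearnerParams,
    ModelKind,
    ValueLearnerAgent,
    ValueState,
    aic,
    choice_prob,
    fit_model,
    model_comparison_table,
    negative_log_likelihood,
    posterior_predictive_match_rate,
    qre_expected_values,
    reward_recode,
    update_values,
)


def make_trials(seq, payoff=DEFAULT_PAYOFF):
    """Build TrialRecords from (participant_choice, opponent_choice) pairs."""
    out = []
    for i, (pc, oc) in enumerate(seq):
        win, pr, orr = resolve_trial(pc, oc, payoff)
        out.append(
            TrialRecord(i, 1, 1, OpponentType.FIX, pc, oc, win, pr, orr)
        )
    return out


H, L = Choice.HIGH, Choice.LOW


class TestRewardRecode:
    @pytest.mark.parametrize(
        "model, win, choice, expected",
        [
            (ModelKind.WRM, True, L, 1.0),
            (ModelKind.WRM, True, H, 1.0),
            (ModelKind.WRM, False, H, 0.0),
            (ModelKind.RL, True, H, 1.0),
            (ModelKind.RL, True, L, 1.0 / 3.0),
            (ModelKind.RL, False, H, 0.0),
        ],
    )
    def test_recode_table(self, model, win, choice, expected):
        assert reward_recode(model, win, choice) == expected

    def test_qre_has_no_recoding(self):
        with pytest.raises(ValueError):
            reward_recode(ModelKind.QRE, True, H)


class TestValueUpdate:
    def test_delta_rule_arithmetic(self):
        s = update_values(ValueState(0.5, 0.5), H, 1.0, 0.4)
        assert s.v_high == pytest.approx(0.7) and s.v_low == 0.5

    def test_zero_alpha_freezes_values(self):
        s = update_values(ValueState(0.3, 0.8), L, 1.0, 0.0)
        assert (s.v_high, s.v_low) == (0.3, 0.8)

    def test_repeated_updates_converge_to_reward(self):
        s = ValueState(0.0, 0.0)
        prev = 0.0
        for _ in range(100):
            s = update_values(s, H, 1.0, 0.3)
            assert s.v_high >= prev
            prev = s.v_high
        assert s.v_high == pytest.approx(1.0, abs=1e-10)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            update_values(ValueState(), H, 1.0, 1.5)


class TestChoiceProb:
    @given(
        v=st.floats(-5, 5),
        beta=st.floats(0, 50),
    )
    @settings(deadline=None)
    def test_probabilities_sum_to_one_and_tie_at_half(self, v, beta):
        p = choice_prob(v, v, beta)
        assert p == 0.5
        p_h = choice_prob(v + 1, v, beta)
        p_l = choice_prob(v, v + 1, beta)
        assert p_h + p_l == pytest.approx(1.0, abs=1e-12)

    def test_beta_zero_is_random(self):
        assert choice_prob(10.0, -10.0, 0.0) == 0.5

    def test_large_beta_is_greedy(self):
        assert choice_prob(1.0, 0.0, 50.0) > 1 - 1e-12


class TestQreValues:
    def test_equilibrium_rate_ties_at_fifteen(self, payoff):
        assert qre_expected_values(0.25, payoff) == (15.0, 15.0)

    @pytest.mark.parametrize("q, expected", [(1.0, (60.0, 0.0)), (0.0, (0.0, 20.0))])
    def test_degenerate_opponent_rates(self, payoff, q, expected):
        assert qre_expected_values(q, payoff) == expected


class TestLikelihood:
    def test_beta_zero_gives_coin_flip_nll(self):
        trials = make_trials([(H, H), (L, H), (H, L), (L, L)] * 12)
        n = len(trials)
        for model in ModelKind:
            params = (
                LearnerParams(None, 0.0)
                if model is ModelKind.QRE
                else LearnerParams(0.4, 0.0)
            )
            assert negative_log_likelihood(model, params, trials) == pytest.approx(
                n * math.log(2), abs=1e-12
            )

    def test_qre_is_beta_invariant_at_equilibrium_opponent(self):
        # opponent at exactly 1/4 HIGH: EVs tie at 15, likelihood flat in beta
        seq = ([(H, H)] * 3 + [(H, L)] * 9 + [(L, H)] * 9 + [(L, L)] * 27)
        trials = make_trials(seq)
        nlls = [
            negative_log_likelihood(ModelKind.QRE, LearnerParams(None, b), trials)
            for b in (0.0, 1.0, 10.0, 50.0)
        ]
        assert max(nlls) - min(nlls) < 1e-12
        assert nlls[0] == pytest.approx(len(trials) * math.log(2), abs=1e-12)

    def test_wrm_five_trial_hand_trace(self):
        """Frozen value from a step-by-step hand computation of the delta rule
        and softmax on five trials (alpha = 0.4, beta = 2, v0 = 0.5)."""
        seq = [(H, H), (H, L), (L, L), (L, H), (H, H)]
        trials = make_trials(seq)
        nll = negative_log_likelihood(
            ModelKind.WRM, LearnerParams(0.4, 2.0), trials, v_init=0.5
        )
        assert nll == pytest.approx(2.967498813904889, abs=1e-10)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            negative_log_likelihood(ModelKind.WRM, LearnerParams(0.4, 1.0), [])


class TestAic:
    def test_two_parameter_models(self):
        assert aic(48 * math.log(2), ModelKind.WRM) == pytest.approx(70.54212933375474)
        assert aic(48 * math.log(2), ModelKind.RL) == pytest.approx(70.54212933375474)

    def test_one_parameter_qre(self):
        assert aic(48 * math.log(2), ModelKind.QRE) == pytest.approx(68.54212933375474)

    def test_perfect_fit(self):
        assert aic(0.0, ModelKind.WRM) == 4.0
        assert aic(0.0, ModelKind.QRE) == 2.0


class TestFit:
    def test_refit_same_seed_is_identical(self):
        rng = np.random.default_rng(21)
        part = ValueLearnerAgent(ModelKind.WRM, 0.35, 5.0)
        trials = play_block(FixAgent(0.25), part, 48, DEFAULT_PAYOFF, rng)
        a = fit_model(ModelKind.WRM, trials, FitConfig(seed=5))
        b = fit_model(ModelKind.WRM, trials, FitConfig(seed=5))
        assert a == b

    def test_bounds_respected_and_converged_flag(self):
        rng = np.random.default_rng(2)
        part = ValueLearnerAgent(ModelKind.RL, 0.3, 4.0)
        trials = play_block(FixAgent(0.25), part, 48, DEFAULT_PAYOFF, rng)
        for model in ModelKind:
            res = fit_model(model, trials, FitConfig(seed=1))
            assert res.converged
            assert 0.0 <= res.params.beta <= 50.0
            if res.params.alpha is not None:
                assert 0.0 <= res.params.alpha <= 1.0
            assert res.aic == pytest.approx(
                2 * (1 if model is ModelKind.QRE else 2) + 2 * res.nll
            )

    def test_degenerate_all_high_choices_drive_beta_to_bound(self):
        # all-HIGH, all-win: values saturate at 1 and the likelihood keeps
        # improving as beta grows, so the fit lands at the box bound
        trials = make_trials([(H, H)] * 48)
        res = fit_model(ModelKind.WRM, trials, FitConfig(seed=0))
        assert res.converged
        assert res.params.beta > 45.0
        assert res.nll < math.log(2) + 1e-6  # only the first (tied) trial costs

    def test_long_sequence_recovers_generating_params(self):
        """480 trials from WRM(0.35, 5) vs FIX: recovered alpha within 0.10
        and beta within 30 percent, median over replicates."""
        errs_a, errs_b = [], []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            part = ValueLearnerAgent(ModelKind.WRM, 0.35, 5.0)
            trials = play_block(FixAgent(0.25), part, 480, DEFAULT_PAYOFF, rng)
            res = fit_model(ModelKind.WRM, trials, FitConfig(seed=seed))
            errs_a.append(abs(res.params.alpha - 0.35))
            errs_b.append(abs(res.params.beta - 5.0) / 5.0)
        assert np.median(errs_a) < 0.10
        assert np.median(errs_b) < 0.30


class TestPosteriorPredictive:
    def test_beta_zero_model_matches_at_chance(self):
        trials = make_trials([(H, H), (L, L)] * 24)
        fit = FitResult(
            ModelKind.WRM, LearnerParams(0.3, 0.0), 48 * math.log(2), 0.0, 48, 1, True
        )
        rng = np.random.default_rng(8)
        rate = posterior_predictive_match_rate(fit, trials, reps=2000, rng=rng)
        assert rate == pytest.approx(0.5, abs=0.02)

    def test_deterministic_data_large_beta_matches_fully(self):
        trials = make_trials([(H, H)] * 48)  # always HIGH, always winning
        rng = np.random.default_rng(8)
        fit = fit_model(ModelKind.WRM, trials, FitConfig(seed=0))
        rate = posterior_predictive_match_rate(fit, trials, reps=500, rng=rng)
        assert rate > 0.95

    def test_self_consistency_above_chance(self):
        rng = np.random.default_rng(77)
        rates = []
        for i in range(10):
            gen = np.random.default_rng(500 + i)
            part = ValueLearnerAgent(ModelKind.WRM, 0.35, 5.0)
            trials = play_block(FixAgent(0.25), part, 48, DEFAULT_PAYOFF, gen)
            res = fit_model(ModelKind.WRM, trials, FitConfig(seed=i))
            rates.append(
                posterior_predictive_match_rate(res, trials, reps=200, rng=rng)
            )
        assert np.mean(rates) > 0.55

    def test_invalid_reps_rejected(self):
        trials = make_trials([(H, H)])
        fit = FitResult(ModelKind.WRM, LearnerParams(0.3, 1.0), 1.0, 6.0, 1, 1, True)
        with pytest.raises(ValueError):
            posterior_predictive_match_rate(
                fit, trials, reps=0, rng=np.random.default_rng(0)
            )


class TestComparisonTable:
    @staticmethod
    def _fit(model, nll):
        params = (
            LearnerParams(None, 1.0)
            if model is ModelKind.QRE
            else LearnerParams(0.3, 1.0)
        )
        return FitResult(model, params, nll, aic(nll, model), 48, 1, True)

    def test_single_participant_table_equals_own_aics(self):
        fits = {
            ("p1", "FIX", m): self._fit(m, 30.0) for m in ModelKind
        }
        table = model_comparison_table(fits)
        assert table.loc["FIX", "WRM"] == pytest.approx(64.0)
        assert table.loc["FIX", "QRE"] == pytest.approx(62.0)
        # equal NLL everywhere: parameter count decides the winner
        assert table.loc["FIX", "best"] == "QRE"

    def test_missing_cells_reported(self):
        fits = {("p1", "FIX", ModelKind.WRM): self._fit(ModelKind.WRM, 30.0)}
        with pytest.raises(ValueError, match="missing"):
            model_comparison_table(fits)

    def test_mean_over_participants(self):
        fits = {}
        for i, nll in enumerate((20.0, 40.0)):
            for m in ModelKind:
                fits[(f"p{i}", "LRN", m)] = self._fit(m, nll)
        table = model_comparison_table(fits)
        assert table.loc["LRN", "WRM"] == pytest.approx(4 + 2 * 30.0)
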