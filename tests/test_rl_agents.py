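"""Decision models: utilities, learning rules, choice rule, dispatch."""

import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ils_rl import rl_agents
from ils_rl.ils_env import RoundFeedback
from ils_rl.rl_agents import (EVParams, ProspectParams, agent_act, decay_update,
                              ev_theta, ev_update, ev_valence, initial_expectancies,
                              option_to_ratio, params_from_dict, prospect_utility,
                              pvl2_utility, pvl_theta, random_model_choose,
                              scale_outcome, softmax_choose, softmax_probabilities)

import oracles

TRACE = json.loads((Path(__file__).parent / "data" / "hand_trace.json").read_text())


class TestScaling:
    def test_identity_scaling(self):
        fb = RoundFeedback(win_W=292.0, loss_L=0.0, property_damage_amount_PD=0.0, income_drop=0.0)
        s = scale_outcome(fb, 292.0)
        assert (s.win, s.loss, s.net_x) == (1.0, 0.0, 1.0)

    def test_arithmetic(self):
        fb = RoundFeedback(win_W=146.0, loss_L=29.2, property_damage_amount_PD=29.2, income_drop=0.0)
        s = scale_outcome(fb, 292.0)
        assert s.win == pytest.approx(0.5)
        assert s.loss == pytest.approx(0.1)
        assert s.net_x == pytest.approx(0.4)

    def test_bad_divisor(self):
        fb = RoundFeedback(0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            scale_outcome(fb, 0.0)


class TestEVPieces:
    @pytest.mark.parametrize("win, loss, w, expected", [
        (1.0, 0.0, 0.0, 1.0),
        (2.0, 2.0, 0.5, 0.0),               # symmetric cancellation
        (1.0, 2.0, 0.728, 0.272 - 0.728 * 2),
    ])
    def test_valence(self, win, loss, w, expected):
        assert ev_valence(win, loss, w) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("ev, v, a, expected", [
        (50.0, -3.0, 0.0, 50.0),   # no learning
        (50.0, -3.0, 1.0, -3.0),   # pure recency
        (50.0, 0.0, 0.5, 25.0),
    ])
    def test_update(self, ev, v, a, expected):
        assert ev_update(ev, v, a) == expected

    @pytest.mark.parametrize("t, c, expected", [(10, 3.7, 1.0), (5, 0.0, 1.0), (30, 1.0, 3.0)])
    def test_ev_theta(self, t, c, expected):
        assert ev_theta(t, c) == pytest.approx(expected)

    @pytest.mark.parametrize("c, expected", [(0.0, 0.0), (1.0, 2.0), (0.789, 3 ** 0.789 - 1)])
    def test_pvl_theta(self, c, expected):
        assert pvl_theta(c) == pytest.approx(expected, abs=1e-12)


class TestProspectUtilities:
    def test_gain_branch_identity(self):
        assert prospect_utility(0.0, 0.5, 2.0) == 0.0
        assert prospect_utility(0.73, 1.0, 2.0) == pytest.approx(0.73)

    def test_loss_branch_published_params(self):
        # |−1|^alpha = 1 regardless of alpha, so utility = −lambda
        assert prospect_utility(-1.0, 0.557, 2.204) == pytest.approx(-2.204)

    def test_pvl2_cases(self):
        assert pvl2_utility(3.0, 3.0, 0.7, 1.0) == pytest.approx(0.0)
        assert pvl2_utility(0.8, 0.0, 1.0, 3.0) == pytest.approx(0.8)
        assert pvl2_utility(1.0, 1.0, 0.851, 4.797) == pytest.approx(1 - 4.797)

    @given(win=st.floats(0, 100), alpha=st.floats(0.01, 1), lam=st.floats(0, 5))
    @settings(max_examples=200, derandomize=True)
    def test_pvl2_reduces_to_prospect_gain_branch(self, win, alpha, lam):
        assert pvl2_utility(win, 0.0, alpha, lam) == pytest.approx(
            prospect_utility(win, alpha, lam), rel=1e-12)

    @given(x=st.floats(0.01, 100), alpha=st.floats(0.01, 1), lam=st.floats(0, 5))
    @settings(max_examples=200, derandomize=True)
    def test_loss_is_lambda_scaled_mirror_of_gain(self, x, alpha, lam):
        assert prospect_utility(-x, alpha, lam) == pytest.approx(
            -lam * prospect_utility(x, alpha, lam), rel=1e-10)

    @given(loss=st.floats(0.01, 100), alpha=st.floats(0.01, 1),
           lam1=st.floats(0, 5), lam2=st.floats(0, 5))
    @settings(max_examples=200, derandomize=True)
    def test_higher_lambda_never_raises_loss_utility(self, loss, alpha, lam1, lam2):
        lo, hi = sorted([lam1, lam2])
        assert pvl2_utility(0.0, loss, alpha, hi) <= pvl2_utility(0.0, loss, alpha, lo) + 1e-12


class TestLearningRules:
    def test_decay_limits(self):
        ev = initial_expectancies()
        full = decay_update(ev, 4, 10.0, 0.0)
        assert full[3] == 10.0 and np.all(full[np.arange(10) != 3] == 0.0)
        none = decay_update(ev, 4, 10.0, 1.0)
        assert none[3] == 60.0 and np.all(none[np.arange(10) != 3] == 50.0)

    def test_decay_hand_value(self):
        out = decay_update(initial_expectancies(), 1, 10.0, 0.5)
        assert out[0] == 35.0 and np.all(out[1:] == 25.0)

    def test_decay_shrinks_all_by_factor_A_at_zero_utility(self, rng):
        ev = rng.normal(size=10)
        out = decay_update(ev, 5, 0.0, 0.37)
        np.testing.assert_allclose(out, 0.37 * ev, rtol=1e-15)

    def test_ev_family_leaves_unchosen_bitwise_unchanged(self, rng):
        params = EVParams(recency_a=0.6, loss_weight_w=0.3, consistency_c=0.5)
        ev = rng.normal(size=10)
        fb = RoundFeedback(100.0, 20.0, 20.0, 0.0)
        _, _, new = agent_act("ev", params, ev, 2, fb, 7, np.random.default_rng(0))
        mask = np.arange(10) != 6
        assert np.array_equal(new[mask], ev[mask])
        assert new[6] != ev[6]


class TestChoiceRule:
    def test_equal_expectancies_uniform(self):
        probs = softmax_probabilities(initial_expectancies(), 1.3)
        np.testing.assert_allclose(probs, 0.1, atol=1e-15)

    def test_theta_zero_uniform(self, rng):
        probs = softmax_probabilities(rng.normal(size=10), 0.0)
        np.testing.assert_allclose(probs, 0.1, atol=1e-15)

    def test_two_option_logistic(self):
        # logistic closed form on an effectively two-option contest
        big = -1e6
        ev = np.array([1.0, 0.0] + [big] * 8)
        probs = softmax_probabilities(ev, 1.0)
        assert probs[0] == pytest.approx(np.e / (1 + np.e), abs=1e-12)

    def test_probabilities_sum_to_one_randomized(self, rng):
        for _ in range(1000):
            ev = rng.normal(scale=rng.uniform(0.1, 50), size=10)
            theta = rng.uniform(0, 5)
            assert abs(softmax_probabilities(ev, theta).sum() - 1.0) < 1e-12

    def test_overflow_safety(self):
        probs = softmax_probabilities(np.array([1e4] * 5 + [-1e4] * 5), 1.0)
        assert np.isfinite(probs).all() and probs.sum() == pytest.approx(1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            softmax_probabilities(np.array([np.nan] * 10), 1.0)

    def test_choose_matches_inverse_cdf(self, scripted_rng_factory):
        ev = initial_expectancies()
        assert softmax_choose(ev, 1.0, scripted_rng_factory([0.05])) == 1
        assert softmax_choose(ev, 1.0, scripted_rng_factory([0.25])) == 3
        assert softmax_choose(ev, 1.0, scripted_rng_factory([0.999])) == 10


class TestRatioMapping:
    @pytest.mark.parametrize("k, lo, hi", [(1, 0.0, 0.1), (6, 0.5, 0.6), (10, 0.9, 1.0)])
    def test_bin_bounds(self, k, lo, hi, rng):
        for _ in range(200):
            r = option_to_ratio(k, rng)
            assert lo <= r < hi

    def test_out_of_range(self, rng):
        with pytest.raises(ValueError):
            option_to_ratio(0, rng)
        with pytest.raises(ValueError):
            option_to_ratio(11, rng)

    def test_single_draw(self, scripted_rng_factory):
        r = scripted_rng_factory([0.5])
        assert option_to_ratio(3, r) == pytest.approx(0.25)
        assert r.i == 1


class TestRandomModel:
    def test_tie_breaks_to_lowest_index(self, scripted_rng_factory):
        r = scripted_rng_factory([0.7] * 10)
        assert random_model_choose(r) == 1

    def test_reproducible(self):
        seq1 = [random_model_choose(np.random.default_rng(5)) for _ in range(3)]
        seq2 = [random_model_choose(np.random.default_rng(5)) for _ in range(3)]
        assert seq1 == seq2


class TestAgentAct:
    def test_first_round_choice_uniform(self):
        # equal initial expectancies: empirical first-choice frequencies ~ 0.1
        rng = np.random.default_rng(42)
        params = ProspectParams(0.5, 2.0, 0.5, 1.0)
        counts = np.zeros(10)
        n = 10_000
        for _ in range(n):
            k, _, _ = agent_act("pvl", params, initial_expectancies(), 1, None, None, rng)
            counts[k - 1] += 1
        se = np.sqrt(0.1 * 0.9 / n)
        np.testing.assert_allclose(counts / n, 0.1, atol=3 * se)

    def test_ev_zero_recency_never_learns(self):
        params = EVParams(recency_a=0.0, loss_weight_w=0.5, consistency_c=0.0)
        ev = initial_expectancies()
        fb = RoundFeedback(100.0, 300.0, 300.0, 0.0)
        for t in range(2, 10):
            _, _, ev = agent_act("ev", params, ev, t, fb, 4, np.random.default_rng(t))
        assert np.all(ev == 50.0)

    def test_mismatched_params_rejected(self):
        with pytest.raises(ValueError):
            agent_act("pvl", EVParams(0.5, 0.5, 0.0), initial_expectancies(),
                      1, None, None, np.random.default_rng(0))
        with pytest.raises(ValueError):
            agent_act("random", EVParams(0.5, 0.5, 0.0), initial_expectancies(),
                      1, None, None, np.random.default_rng(0))

    @pytest.mark.parametrize("model_id", ["ev", "pvl", "evpu", "pvl2"])
    def test_scripted_trace_matches_frozen_hand_computation(
            self, model_id, scripted_rng_factory):
        """3-round scripted trace equals the independently computed fixture."""
        if model_id == "ev":
            params = EVParams(recency_a=0.5, loss_weight_w=0.5, consistency_c=0.0)
        else:
            params = params_from_dict(model_id, {
                "shape_alpha": 0.5, "loss_aversion_lambda": 2.0,
                "recency_A": 0.5, "consistency_c": 1.0})
        feedbacks = [None,
                     RoundFeedback(1.0, 0.5, 0.5, 0.0),
                     RoundFeedback(0.2, 1.0, 1.0, 0.0)]
        expected = TRACE[model_id]
        # the frozen fixture itself must agree with the runtime oracle
        runtime = oracles.hand_trace(model_id)
        np.testing.assert_allclose(runtime["expectancies"], expected["expectancies"],
                                   rtol=0, atol=1e-12)
        ev = initial_expectancies()
        last_k = None
        for t in (1, 2, 3):
            rng = scripted_rng_factory([oracles.TRACE_U_CHOICE[t - 1], 0.5])
            k, ratio, ev = agent_act(model_id, params, ev, t, feedbacks[t - 1],
                                     last_k, rng, scale_divisor=1.0)
            np.testing.assert_allclose(ev, expected["expectancies"][t - 1], atol=1e-10, rtol=0)
            theta = (ev_theta(t, params.consistency_c) if model_id in ("ev", "evpu")
                     else pvl_theta(params.consistency_c))
            np.testing.assert_allclose(softmax_probabilities(ev, theta),
                                       expected["probs"][t - 1], atol=1e-10, rtol=0)
            assert k == expected["chosen"][t - 1]
            assert ratio == pytest.approx((k - 1 + 0.5) / 10)
            last_k = k


class TestParamValidation:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            EVParams(recency_a=1.2, loss_weight_w=0.5, consistency_c=0.0)
        with pytest.raises(ValueError):
            ProspectParams(0.5, 6.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            ProspectParams(0.5, 2.0, 0.5, -1.0)          # pvl-style c >= 0
        ProspectParams(0.5, 2.0, 0.5, -1.0, ev_style_c=True)  # evpu allows it

    def test_params_from_dict_round_trip(self):
        p = params_from_dict("evpu", {"shape_alpha": 0.88, "loss_aversion_lambda": 0.129,
                                      "consistency_c": -0.836, "recency_A": 0.954})
        assert p.ev_style_c and p.consistency_c == -0.836
        assert params_from_dict("random", {}) is None
        with pytest.raises(ValueError):
            params_from_dict("random", {"x": 1})
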