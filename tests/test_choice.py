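"""Valuation, probability weighting, softmax choice, and the likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import urnlearn as ul
from urnlearn.choice import TrialData
from urnlearn.exceptions import IncompleteDataError, InvalidProbabilityError

M4 = ul.DEFAULT_GENERATING_PARAMS["M4"]


def small_design():
    return ul.TaskDesign(bins_per_session=3, state_counts=(2, 5, 10))


class TestValueFunction:
    def test_identity_at_unit_parameters(self):
        x = np.linspace(-50, 50, 101)
        np.testing.assert_allclose(ul.value_fn(x, alpha=1.0, lam=1.0), x,
                                   atol=1e-12)

    def test_gain_with_table_sensitivity(self):
        assert ul.value_fn(10.0, alpha=0.69) == pytest.approx(10**0.69)
        assert ul.value_fn(10.0, alpha=0.69) == pytest.approx(4.898, abs=1e-3)

    def test_loss_aversion_scales_mirror_image(self):
        v_gain = ul.value_fn(10.0, alpha=0.69, lam=2.57)
        v_loss = ul.value_fn(-10.0, alpha=0.69, lam=2.57)
        assert v_loss == pytest.approx(-2.57 * v_gain)
        assert v_loss == pytest.approx(-12.59, abs=1e-2)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.2, 2.0), st.floats(0.2, 9.0))
    def test_strictly_increasing_with_kink_only_at_zero(self, alpha, lam):
        x = np.linspace(-20, 20, 401)
        v = ul.value_fn(x, alpha=alpha, lam=lam)
        assert np.all(np.diff(v) > 0)
        assert ul.value_fn(0.0, alpha=alpha, lam=lam) == 0.0
        # continuity at the kink: the jump shrinks like (1 + lam) * eps^alpha
        eps = 1e-9
        assert abs(ul.value_fn(eps, alpha, lam)
                   - ul.value_fn(-eps, alpha, lam)) <= \
            (1 + lam) * eps**alpha * (1 + 1e-9)


class TestWeightFunction:
    def test_linear_limit(self):
        p = np.linspace(0, 1, 11)
        np.testing.assert_allclose(ul.weight_fn(p, gamma=1.0), p, atol=1e-12)

    @pytest.mark.parametrize("gamma", [0.3, 0.61, 0.89, 1.0, 1.5, 2.0])
    def test_endpoints_preserved(self, gamma):
        assert ul.weight_fn(0.0, gamma) == 0.0
        assert ul.weight_fn(1.0, gamma) == 1.0

    def test_tversky_kahneman_value(self):
        # independent scalar evaluation: 0.1^.61/(0.1^.61 + 0.9^.61)^(1/.61)
        g = 0.61
        expected = 0.1**g / (0.1**g + 0.9**g) ** (1 / g)
        assert ul.weight_fn(0.1, 0.61) == pytest.approx(expected, abs=1e-12)
        assert ul.weight_fn(0.1, 0.61) == pytest.approx(0.186, abs=5e-3)

    def test_rejects_probabilities_outside_unit_interval(self):
        with pytest.raises(InvalidProbabilityError):
            ul.weight_fn(1.2, 0.8)

    @pytest.mark.parametrize("gamma", [0.3, 0.7, 1.3, 2.0])
    def test_monotone_within_constrained_range(self, gamma):
        p = np.linspace(0, 1, 201)
        assert np.all(np.diff(ul.weight_fn(p, gamma)) > 0)


class TestGambleEV:
    def test_certainty_case(self):
        assert ul.gamble_ev([1.0], [60.0], 50.0, spec="M2") == pytest.approx(10.0)

    def test_hand_evaluated_two_state_case(self):
        ev = ul.gamble_ev([0.5, 0.5], [40.0, 60.0], 50.0,
                          ul.ValueParams(alpha=1.0, lam=2.0), spec="M4")
        assert ev == pytest.approx(0.5 * (-2 * 10) + 0.5 * 10)

    def test_payoffs_at_price_give_zero(self):
        ev = ul.gamble_ev(np.full(5, 0.2), np.full(5, 37.0), 37.0,
                          ul.ValueParams(0.7, 2.5, 0.9), spec="M5")
        assert ev == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(2, 10), st.integers(0, 10_000))
    def test_reduces_to_expected_value_at_unit_parameters(self, K, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(K))
        x = r.uniform(10, 99, K)
        price = r.uniform(10, 99)
        ev = ul.gamble_ev(p, x, price, ul.ValueParams(1.0, 1.0, 1.0),
                          spec="M5")
        assert ev == pytest.approx(float(np.sum(p * (x - price))),
                                   abs=1e-12)


class TestBuyProbability:
    def test_midpoint_and_logistic_value(self):
        assert ul.buy_probability(0.0, ul.ChoiceParams(0.0, 1.0)) == 0.5
        assert ul.buy_probability(2.0, ul.ChoiceParams(0.0, 1.0)) == \
            pytest.approx(1 / (1 + math.exp(-2)))

    def test_monotone_in_ev_and_clipped(self):
        q = ul.buy_probability(np.linspace(-100, 100, 51),
                               ul.ChoiceParams(0.0, 1.0))
        assert np.all(np.diff(q) >= 0)
        assert q[0] >= 1e-9 and q[-1] <= 1 - 1e-9


class TestDatasetLoglik:
    def test_single_even_odds_trial(self):
        sessions = ul.simulate_cohort(small_design(), 1, "M2",
                                      {"beta0": 0.0, "beta1": 0.0}, seed=3)
        td = TrialData.from_sessions(sessions, ul.MODEL_SPECS["M2"])
        ll = td.loglik({"beta0": 0.0, "beta1": 0.0})
        # slope 0 makes every active trial a fair coin
        assert ll == pytest.approx(td.n_active * math.log(0.5))

    def test_missing_decisions_raise(self, rng):
        sess = ul.simulate_session(small_design(), rng)
        with pytest.raises(IncompleteDataError):
            ul.dataset_loglik([sess], "M4", M4)

    @pytest.mark.parametrize("tag", ["M2", "M3", "M4", "M4a", "M4b", "M5"])
    def test_straight_line_oracle_agreement(self, tag):
        """An independent plain-Python replay reproduces the pipeline
        log-likelihood to 1e-10 for every model variant."""
        params = dict(ul.DEFAULT_GENERATING_PARAMS[tag])
        if tag == "M5":
            params["gamma"] = 0.8  # exercise the curved weighting path
        sessions = ul.simulate_cohort(small_design(), 1, tag, params, seed=11)
        ll = ul.dataset_loglik(sessions, tag, params)
        assert ll == pytest.approx(_oracle_loglik(sessions[0], tag, params),
                                   abs=1e-10)

    def test_m4b_ev_ignores_draw_history(self, rng):
        """Shuffling the draw stream cannot move the no-learning model."""
        sessions = ul.simulate_cohort(small_design(), 1, "M4b",
                                      ul.DEFAULT_GENERATING_PARAMS["M4b"],
                                      seed=21)
        sess = sessions[0]
        ll = ul.dataset_loglik([sess], "M4b", ul.DEFAULT_GENERATING_PARAMS["M4b"])
        shuffled_draws = list(rng.permutation(np.array(sess.draws, dtype=object)))
        shuffled = ul.Session(sess.subject, sess.bins, shuffled_draws,
                              sess.trials, sess.design)
        ll2 = ul.dataset_loglik([shuffled], "M4b",
                                ul.DEFAULT_GENERATING_PARAMS["M4b"])
        assert ll2 == pytest.approx(ll, abs=1e-12)

    def test_trial_order_permutation_invariance(self, rng):
        sessions = ul.simulate_cohort(small_design(), 1, "M4", M4, seed=13)
        sess = sessions[0]
        ll = ul.dataset_loglik([sess], "M4", M4)
        perm_trials = list(rng.permutation(np.array(sess.trials, dtype=object)))
        permuted = ul.Session(sess.subject, sess.bins, sess.draws,
                              perm_trials, sess.design)
        assert ul.dataset_loglik([permuted], "M4", M4) == \
            pytest.approx(ll, abs=1e-12)


def _oracle_loglik(session, tag, params):
    """Straight-line reimplementation of the likelihood, kept deliberately
    naive (dicts, python floats, explicit loops)."""
    spec = ul.MODEL_SPECS[tag]
    total = 0.0
    for bin_id, bc in enumerate(session.bins):
        counts = [0] * bc.K
        for stage in (1, 2):
            if stage == 2:
                if spec.inference in ("observation",):
                    counts = [0] * bc.K
            stage_draws = sorted(
                (d for d in session.draws
                 if d.bin_id == bin_id and d.stage == stage),
                key=lambda d: d.t,
            )
            V = None
            for d in stage_draws:
                if spec.inference == "reinforcement":
                    if V is None:
                        V = d.payoff
                    else:
                        V = V + params["eta"] * (d.payoff - V)
                elif spec.inference != "none":
                    counts[d.state] += 1
            t = sum(counts)
            p_hat = [(c + 1.0) / (t + bc.K) for c in counts]
            pmap = bc.payoff_map(stage)
            for c in session.trials:
                if not (c.bin_id == bin_id and c.stage == stage
                        and c.condition == "active"):
                    continue
                if spec.inference == "reinforcement":
                    ev = V - c.price
                else:
                    ev = 0.0
                    for k in range(bc.K):
                        w = p_hat[k]
                        if spec.weight_form == "curved":
                            g = params["gamma"]
                            w = p_hat[k]**g / (
                                p_hat[k]**g + (1 - p_hat[k])**g
                            ) ** (1 / g)
                        net = pmap[k] - c.price
                        if spec.value_form == "linear":
                            v = net
                        elif net >= 0:
                            v = net ** params["alpha"]
                        else:
                            v = -params["lam"] * (-net) ** params["alpha"]
                        ev += w * v
                q = 1.0 / (1.0 + math.exp(-(params["beta0"]
                                            + params["beta1"] * ev)))
                q = min(max(q, 1e-9), 1 - 1e-9)
                total += math.log(q) if c.decision == 1 else math.log(1 - q)
    return total
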