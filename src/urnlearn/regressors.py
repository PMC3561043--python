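"""Trial-wise uncertainty quantities and event-table export.

These are the covariates a neuroimaging analysis would regress brain
activity on, computed here from the fitted behavioral model and exported
as BIDS-style ``events.tsv`` tables (onset, duration, trial_type, one
column per parametric modulator):

* stimulus probability — the probability the learner assigned to the
  currently displayed payoff *before* updating on it (how expected the
  evidence was);
* prediction error — the change in the gamble's subjective expected value
  produced by one new draw, computed price-free on the raw payoffs since
  no price is posted during sampling;
* outcome entropy — Shannon entropy (nats) of the end-of-stage state
  probability estimates: expected uncertainty about the next draw;
* choice entropy — binary entropy of the model's buy probability:
  decision conflict;
* net payoff — the stage's realized total payoff net of prices, shown as
  feedback after the six choices.

Onsets are synthetic (configurable stimulus duration and inter-stimulus
interval); the module does not model a scanner timeline. Modulators are
mean-centered within subject before export, the usual parametric-
modulation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

from .beliefs import (
    BeliefState,
    init_beliefs,
    observe,
    point_estimates,
    predictive_probability,
    stage_transition,
)
from .choice import ChoiceParams, TrialData, ValueParams, get_spec, value_fn
from .exceptions import InconsistentStateError, InvalidDistributionError


@dataclass(frozen=True)
class TimingParams:
    """Synthetic event timing (seconds)."""

    stimulus_duration: float = 1.0
    inter_stimulus_interval: float = 1.0
    decision_duration: float = 3.0
    feedback_duration: float = 2.0


def outcome_entropy(p) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidDistributionError(
            "outcome_entropy needs a probability vector"
        )
    return float(_shannon_entropy(p))


def choice_entropy(q: float) -> float:
    """Binary entropy (nats) of the buy probability."""
    if not 0.0 <= q <= 1.0:
        raise InvalidDistributionError(f"q must lie in [0, 1], got {q}")
    return outcome_entropy(np.array([q, 1.0 - q]))


def _subjective_ev(beliefs: BeliefState, payoff_map: np.ndarray,
                   value_params: ValueParams | None) -> float:
    p = point_estimates(beliefs)
    if value_params is None:
        v = np.asarray(payoff_map, float)
    else:
        v = value_fn(payoff_map, value_params.alpha, value_params.lam)
    return float(np.sum(p * v))


def prediction_error(
    beliefs_before: BeliefState,
    beliefs_after: BeliefState,
    payoff_map: np.ndarray,
    value_params: ValueParams | None = None,
) -> float:
    """Change in the gamble's subjective EV from one new draw.

    Evaluated on raw payoffs (no price is posted during sampling). For a
    non-learning belief variant the beliefs never move, so the prediction
    error is identically zero.
    """
    before = np.asarray(beliefs_before.counts)
    after = np.asarray(beliefs_after.counts)
    diff = after - before
    no_update = beliefs_before.variant == "none" and np.all(diff == 0)
    one_step = diff.sum() == 1 and np.all((diff == 0) | (diff == 1))
    if not (one_step or no_update):
        raise InconsistentStateError(
            "belief states must differ by exactly one observation"
        )
    return _subjective_ev(beliefs_after, payoff_map, value_params) - \
        _subjective_ev(beliefs_before, payoff_map, value_params)


def build_event_table(
    session,
    spec="M4",
    params: dict[str, float] | None = None,
    timing: TimingParams | None = None,
    alpha0: float = 1.0,
) -> pd.DataFrame:
    """One subject's event table with mean-centered parametric modulators.

    Rows: one ``stimulus`` per draw (stim_probability, prediction_error),
    one ``decision`` per choice trial (ev, outcome_entropy, choice_entropy),
    one ``feedback`` per stage (net_payoff). ``params`` are the fitted
    model parameters used for valuation and choice probabilities.
    """
    spec = get_spec(spec)
    if spec.inference == "reinforcement":
        raise ValueError("event tables require a probability-based model")
    params = params or {}
    vp = ValueParams(params.get("alpha", 1.0), params.get("lam", 1.0),
                     params.get("gamma", 1.0))
    use_value = spec.value_form == "prospect"
    cp = ChoiceParams(params.get("beta0", 0.0), params.get("beta1", 1.0))
    timing = timing or TimingParams()

    td = TrialData.from_sessions([session], spec, alpha0=alpha0,
                                 include_control=True)
    all_params = {"beta0": cp.beta0, "beta1": cp.beta1, "lam": vp.lam,
                  "alpha": vp.alpha, "gamma": vp.gamma}
    model_params = {n: all_params[n] for n in spec.param_names}
    ev_arr = td.expected_values(model_params)
    q_arr = td.buy_probabilities(model_params)
    trial_pos = {id(c): i for i, c in enumerate(td.trials_in_order(session))}

    draws_by = {}
    for d in session.draws:
        draws_by.setdefault((d.bin_id, d.stage), []).append(d)
    trials_by = {}
    for c in session.trials:
        trials_by.setdefault((c.bin_id, c.stage), []).append(c)

    rows = []
    onset = 0.0
    step = timing.stimulus_duration + timing.inter_stimulus_interval
    for bin_id, bc in enumerate(session.bins):
        beliefs = init_beliefs(
            bc.K, alpha0,
            spec.inference if spec.inference != "none" else "none",
        )
        for stage in (1, 2):
            if stage == 2:
                beliefs = stage_transition(beliefs)
            pmap = bc.payoff_map(stage)
            for d in sorted(draws_by.get((bin_id, stage), []),
                            key=lambda d: d.t):
                p_pre = predictive_probability(beliefs, d.state)
                updated = observe(beliefs, d.state)
                pe = prediction_error(
                    beliefs, updated, pmap, vp if use_value else None
                )
                beliefs = updated
                rows.append({
                    "onset": onset, "duration": timing.stimulus_duration,
                    "trial_type": "stimulus", "bin": bin_id, "stage": stage,
                    "stim_probability": p_pre, "prediction_error": pe,
                    "payoff": d.payoff,
                })
                onset += step
            h_outcome = outcome_entropy(point_estimates(beliefs))
            net_payoff = 0.0
            for c in sorted(trials_by.get((bin_id, stage), []),
                            key=lambda c: c.choice_idx):
                i = trial_pos[id(c)]
                q = float(q_arr[i])
                rows.append({
                    "onset": onset, "duration": timing.decision_duration,
                    "trial_type": "decision", "bin": bin_id, "stage": stage,
                    "ev": float(ev_arr[i]), "outcome_entropy": h_outcome,
                    "choice_entropy": choice_entropy(q),
                })
                onset += timing.decision_duration + \
                    timing.inter_stimulus_interval
                if c.decision == 1:
                    net_payoff += c.outcome_payoff - c.price
            rows.append({
                "onset": onset, "duration": timing.feedback_duration,
                "trial_type": "feedback", "bin": bin_id, "stage": stage,
                "net_payoff": net_payoff,
            })
            onset += timing.feedback_duration + \
                timing.inter_stimulus_interval

    table = pd.DataFrame(rows)
    modulators = ["stim_probability", "prediction_error", "ev",
                  "outcome_entropy", "choice_entropy", "net_payoff"]
    for col in modulators:
        if col in table:
            mask = table[col].notna()
            table.loc[mask, col] -= table.loc[mask, col].mean()
    return table


def write_event_table(table: pd.DataFrame, path) -> None:
    """Write a BIDS-style events.tsv (UTF-8, '.' decimal, 'n/a' missing)."""
    table.to_csv(path, sep="\t", index=False, na_rep="n/a",
                 encoding="utf-8")
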