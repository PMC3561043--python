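"""Learning-phase probability estimators.

Three count-based Dirichlet-multinomial variants differ only in what
survives a stage boundary:

* ``hidden_state`` — counts over inferred ball colors; persist across the
  resampling boundary (the bin's composition has not changed).
* ``observation`` — counts over observed payoffs; since the payoff legend
  is redrawn each stage, counts reset at every stage start. Within a stage
  payoffs and states are in bijection, so the same count vector serves.
* ``none`` — no learning; estimates stay at the equiprobable prior.

A delta-rule forecaster tracks the expected payoff directly (bypassing
probabilities): the first payoff of a stage initializes the forecast, and
each subsequent payoff moves it by a learning rate times the prediction
error. It re-initializes at every stage start because it forecasts
payoffs, which change at resampling.

Estimates are posterior means under a symmetric Dirichlet(alpha0) prior:
p_hat_k = (n_k + alpha0) / (t + K * alpha0). Counts are stored as integers
and estimates computed on demand, so there is no incremental float drift
and estimates depend on the counts only, never on observation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InvalidStateCountError, UnknownPayoffError

VARIANTS = ("hidden_state", "observation", "none")


@dataclass(frozen=True)
class BeliefState:
    """Running observation tallies under a symmetric Dirichlet prior."""

    K: int
    counts: tuple[int, ...]
    alpha0: float = 1.0
    variant: str = "hidden_state"


@dataclass(frozen=True)
class RLState:
    """Delta-rule payoff forecast. ``V is None`` means not yet initialized."""

    V: float | None = None
    eta: float = 0.5


def init_beliefs(
    K: int, alpha0: float = 1.0, variant: str = "hidden_state"
) -> BeliefState:
    """Fresh beliefs for a new bin: zero counts, equiprobable prior mean."""
    if K < 2:
        raise InvalidStateCountError(f"K must be >= 2, got {K}")
    if alpha0 <= 0:
        raise ValueError(f"alpha0 must be > 0, got {alpha0}")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    return BeliefState(K=K, counts=(0,) * K, alpha0=alpha0, variant=variant)


def infer_state(payoff: float, payoff_map: np.ndarray) -> int:
    """Invert the state->payoff bijection for the observed payoff."""
    hits = np.flatnonzero(np.asarray(payoff_map) == payoff)
    if len(hits) != 1:
        raise UnknownPayoffError(
            f"payoff {payoff} not uniquely present in map {payoff_map}"
        )
    return int(hits[0])


def observe(beliefs: BeliefState, state: int) -> BeliefState:
    """Record one observation of ``state`` (no-op for the none variant)."""
    if not 0 <= state < beliefs.K:
        raise IndexError(f"state {state} out of range for K={beliefs.K}")
    if beliefs.variant == "none":
        return beliefs
    counts = list(beliefs.counts)
    counts[state] += 1
    return replace(beliefs, counts=tuple(counts))


def stage_transition(beliefs: BeliefState, new_bin: bool = False) -> BeliefState:
    """Apply the stage-boundary rule for the belief variant.

    At a resampling boundary within the same bin, hidden-state counts are
    kept and observation counts are zeroed; a new bin zeroes counts for
    every variant.
    """
    if new_bin or beliefs.variant == "observation":
        return replace(beliefs, counts=(0,) * beliefs.K)
    return beliefs


def point_estimates(beliefs: BeliefState) -> np.ndarray:
    """Posterior-mean probability of each state."""
    n = np.asarray(beliefs.counts, dtype=float)
    t = n.sum()
    return (n + beliefs.alpha0) / (t + beliefs.K * beliefs.alpha0)


def predictive_probability(beliefs: BeliefState, state: int) -> float:
    """Probability the model assigned to ``state`` before seeing it.

    Callers pass the beliefs held *before* incorporating the current
    draw, so the value reflects how expected (or surprising) the stimulus
    was at the moment it appeared.
    """
    if not 0 <= state < beliefs.K:
        raise IndexError(f"state {state} out of range for K={beliefs.K}")
    return float(point_estimates(beliefs)[state])


def rl_update(state: RLState, payoff: float) -> RLState:
    """Delta-rule update: V <- V + eta * (payoff - V); first payoff sets V."""
    if not 0.0 <= state.eta <= 1.0:
        raise ValueError(f"learning rate must lie in [0, 1], got {state.eta}")
    if state.V is None:
        return replace(state, V=float(payoff))
    return replace(state, V=state.V + state.eta * (payoff - state.V))


def rl_reset(state: RLState) -> RLState:
    """Clear the forecast at a stage start (payoffs are about to change)."""
    return replace(state, V=None)
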