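"""Decision-phase machinery: valuation, softmax choice, and likelihood.

The model family is indexed by its number of free parameters:

========  =========  ===========  ===============  ==========================
tag       value      weighting    inference        parameters
========  =========  ===========  ===============  ==========================
M2        linear     identity     hidden_state     beta0, beta1
M3        linear     identity     reinforcement    beta0, beta1, eta
M4        prospect   identity     hidden_state     beta0, beta1, lam, alpha
M4a       prospect   identity     observation      beta0, beta1, lam, alpha
M4b       prospect   identity     none             beta0, beta1, lam, alpha
M5        prospect   curved       hidden_state     beta0, beta1, lam, alpha,
                                                   gamma
========  =========  ===========  ===============  ==========================

A gamble's expected value at price P is sum_k w(p_hat_k) * v(x_k - P),
where p_hat is the learner's end-of-stage state-probability estimate and
x_k the stage's payoff for state k. The prospect-theory value function is
v(x) = x**alpha for gains and -lam * (-x)**alpha for losses (one shared
diminishing-sensitivity exponent; the kink at zero is the only
non-differentiability). Probability weighting, used by M5 only, is the
one-parameter Tversky-Kahneman form. The buy probability is
logistic(beta0 + beta1 * EV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .beliefs import (
    init_beliefs,
    observe,
    point_estimates,
    rl_reset,
    rl_update,
    RLState,
    stage_transition,
)
from .exceptions import (
    IncompleteDataError,
    InvalidProbabilityError,
    MissingParameterError,
)

#: Clipping bound on buy probabilities, protecting log-likelihoods from -inf.
Q_CLIP = 1e-9


@dataclass(frozen=True)
class ValueParams:
    """Prospect-theory valuation parameters."""

    alpha: float = 1.0  # diminishing sensitivity, (0, 2]
    lam: float = 1.0  # loss aversion, (0, 10]
    gamma: float = 1.0  # probability-weighting curvature, [0.3, 2]


@dataclass(frozen=True)
class ChoiceParams:
    """Logistic (softmax) choice parameters."""

    beta0: float = 0.0  # intercept, logit units
    beta1: float = 1.0  # slope, logit units per value unit


@dataclass(frozen=True)
class ModelSpec:
    tag: str
    value_form: str  # "linear" | "prospect"
    weight_form: str  # "identity" | "curved"
    inference: str  # "hidden_state" | "observation" | "none" | "reinforcement"
    n_params: int
    param_names: tuple[str, ...]


MODEL_SPECS: dict[str, ModelSpec] = {
    "M2": ModelSpec("M2", "linear", "identity", "hidden_state", 2,
                    ("beta0", "beta1")),
    "M3": ModelSpec("M3", "linear", "identity", "reinforcement", 3,
                    ("beta0", "beta1", "eta")),
    "M4": ModelSpec("M4", "prospect", "identity", "hidden_state", 4,
                    ("beta0", "beta1", "lam", "alpha")),
    "M4a": ModelSpec("M4a", "prospect", "identity", "observation", 4,
                     ("beta0", "beta1", "lam", "alpha")),
    "M4b": ModelSpec("M4b", "prospect", "identity", "none", 4,
                     ("beta0", "beta1", "lam", "alpha")),
    "M5": ModelSpec("M5", "prospect", "curved", "hidden_state", 5,
                    ("beta0", "beta1", "lam", "alpha", "gamma")),
}


def get_spec(spec) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    return MODEL_SPECS[spec]


def check_params(spec, params: dict[str, float]) -> None:
    spec = get_spec(spec)
    missing = [p for p in spec.param_names if p not in params]
    if missing:
        raise MissingParameterError(
            f"model {spec.tag} requires parameters {missing}"
        )


def value_fn(x, alpha: float = 1.0, lam: float = 1.0, linear: bool = False):
    """Subjective value of a net payoff; elementwise over arrays."""
    x = np.asarray(x, dtype=float)
    if linear:
        return x
    out = np.where(x >= 0, np.abs(x) ** alpha, -lam * np.abs(x) ** alpha)
    return out if out.shape else float(out)


def weight_fn(p, gamma: float = 1.0, identity: bool = False):
    """Tversky-Kahneman decision weight w(p) = p^g / (p^g + (1-p)^g)^(1/g)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidProbabilityError("probabilities must lie in [0, 1]")
    if identity or gamma == 1.0:
        return p if p.shape else float(p)
    num = p**gamma
    out = num / (num + (1 - p) ** gamma) ** (1 / gamma)
    return out if out.shape else float(out)


def gamble_ev(
    p_hat,
    payoffs,
    price: float,
    value_params: ValueParams | None = None,
    spec="M4",
) -> float:
    """Expected value of buying: sum_k w(p_hat_k) * v(x_k - price)."""
    spec = get_spec(spec)
    vp = value_params or ValueParams()
    p_hat = np.asarray(p_hat, dtype=float)
    payoffs = np.asarray(payoffs, dtype=float)
    if p_hat.shape != payoffs.shape:
        raise ValueError("p_hat and payoffs must have the same length")
    w = weight_fn(p_hat, vp.gamma, identity=spec.weight_form == "identity")
    v = value_fn(payoffs - price, vp.alpha, vp.lam,
                 linear=spec.value_form == "linear")
    return float(np.sum(w * v))


def forecast_ev(V: float, price: float) -> float:
    """Reinforcement-model valuation: linear value of the forecast net of price."""
    return V - price


def buy_probability(ev, choice_params: ChoiceParams):
    """Softmax buy probability, clipped away from 0 and 1 for stability."""
    q = expit(choice_params.beta0 + choice_params.beta1 * np.asarray(ev, float))
    q = np.clip(q, Q_CLIP, 1 - Q_CLIP)
    return q if q.shape else float(q)


# ---------------------------------------------------------------------------
# Dataset likelihood


def _forecast_weights(lengths: np.ndarray, eta: float) -> np.ndarray:
    """Closed-form weights of each draw in the end-of-stage delta-rule forecast.

    For a stage of length L, V_L = (1-eta)^(L-1) x_1
    + eta * sum_{t=2..L} (1-eta)^(L-t) x_t. Returns a (n_stages, max_L)
    matrix with zeros past each stage's length.
    """
    max_len = int(lengths.max())
    t = np.arange(1, max_len + 1)
    W = np.zeros((len(lengths), max_len))
    for i, L in enumerate(lengths):
        if eta == 0.0:
            W[i, 0] = 1.0
            continue
        w = eta * (1 - eta) ** (L - t[:L])
        w[0] = (1 - eta) ** (L - 1)
        W[i, :L] = w
    return W


class TrialData:
    """Pre-digested choice trials for fast repeated likelihood evaluation.

    For the count-based learners the end-of-stage probability estimates do
    not depend on any fitted parameter, so they are computed once at
    construction by replaying each bin's draw stream; the likelihood is
    then a few vectorized array operations per evaluation. For the
    reinforcement model the per-stage payoff sequences are padded into a
    matrix and the end-of-stage forecast is a closed-form weighted sum, so
    the learning-rate dependence stays cheap too.
    """

    def __init__(self, spec: ModelSpec, alpha0: float = 1.0):
        self.spec = spec
        self.alpha0 = alpha0
        self._trials = []  # flat trial refs, session order
        self._p_hat = []  # per-trial estimate vector (count models)
        self._payoffs = []  # per-trial stage payoff map
        self._price = []
        self._decision = []
        self._active = []
        self._stage_payoff_seqs = []  # reinforcement: per-stage sequences
        self._trial_stage_idx = []  # trial -> stage row

    @classmethod
    def from_sessions(
        cls, sessions, spec, alpha0: float = 1.0, include_control: bool = False
    ) -> "TrialData":
        spec = get_spec(spec)
        td = cls(spec, alpha0)
        rl = spec.inference == "reinforcement"
        for sess in sessions:
            draws_by = {}
            for d in sess.draws:
                draws_by.setdefault((d.bin_id, d.stage), []).append(d)
            trials_by = {}
            for c in sess.trials:
                trials_by.setdefault((c.bin_id, c.stage), []).append(c)
            for bin_id, bc in enumerate(sess.bins):
                if not rl:
                    beliefs = init_beliefs(
                        bc.K, alpha0,
                        spec.inference if spec.inference != "none" else "none",
                    )
                for stage in (1, 2):
                    stage_draws = sorted(
                        draws_by.get((bin_id, stage), []), key=lambda d: d.t
                    )
                    if rl:
                        seq = [d.payoff for d in stage_draws]
                        td._stage_payoff_seqs.append(seq)
                        stage_idx = len(td._stage_payoff_seqs) - 1
                    else:
                        if stage == 2:
                            beliefs = stage_transition(beliefs)
                        for d in stage_draws:
                            beliefs = observe(beliefs, d.state)
                        p_hat = point_estimates(beliefs)
                    pmap = bc.payoff_map(stage)
                    for c in sorted(
                        trials_by.get((bin_id, stage), []),
                        key=lambda c: c.choice_idx,
                    ):
                        active = c.condition == "active"
                        if not (active or include_control):
                            continue
                        td._trials.append(c)
                        td._active.append(active)
                        td._price.append(c.price)
                        td._decision.append(
                            -1 if c.decision is None else c.decision
                        )
                        if rl:
                            td._p_hat.append(None)
                            td._payoffs.append(None)
                            td._trial_stage_idx.append(stage_idx)
                        else:
                            td._p_hat.append(p_hat)
                            td._payoffs.append(pmap)
                            td._trial_stage_idx.append(-1)
        td._finalize()
        return td

    def _finalize(self) -> None:
        self._price_arr = np.asarray(self._price, float)
        self._decision_arr = np.asarray(self._decision, int)
        self._active_arr = np.asarray(self._active, bool)
        if self.spec.inference == "reinforcement":
            lengths = np.asarray(
                [len(s) for s in self._stage_payoff_seqs], int
            )
            max_len = int(lengths.max()) if len(lengths) else 0
            X = np.zeros((len(lengths), max_len))
            for i, s in enumerate(self._stage_payoff_seqs):
                X[i, : len(s)] = s
            self._stage_lengths = lengths
            self._stage_matrix = X
            self._trial_stage_arr = np.asarray(self._trial_stage_idx, int)
            self._groups = []
        else:
            # group trials by K for vectorized evaluation
            ks = np.asarray([len(p) for p in self._p_hat], int)
            self._groups = []
            for K in np.unique(ks):
                idx = np.flatnonzero(ks == K)
                P = np.stack([self._p_hat[i] for i in idx])
                X = np.stack([self._payoffs[i] for i in idx])
                self._groups.append((idx, P, X))

    def __len__(self) -> int:
        return len(self._trials)

    @property
    def n_active(self) -> int:
        return int(self._active_arr.sum())

    def trials_in_order(self, session) -> list:
        return list(self._trials)

    def expected_values(self, params: dict[str, float]) -> np.ndarray:
        """End-of-stage gamble EV per trial, in stored trial order."""
        check_params(self.spec, params)
        ev = np.empty(len(self), float)
        if self.spec.inference == "reinforcement":
            W = _forecast_weights(self._stage_lengths, params["eta"])
            V = (W * self._stage_matrix).sum(axis=1)
            ev[:] = V[self._trial_stage_arr] - self._price_arr
            return ev
        linear = self.spec.value_form == "linear"
        identity = self.spec.weight_form == "identity"
        alpha = params.get("alpha", 1.0)
        lam = params.get("lam", 1.0)
        gamma = params.get("gamma", 1.0)
        for idx, P, X in self._groups:
            w = P if identity else weight_fn(P, gamma)
            net = X - self._price_arr[idx][:, None]
            v = net if linear else value_fn(net, alpha, lam)
            ev[idx] = (w * v).sum(axis=1)
        return ev

    def buy_probabilities(self, params: dict[str, float]) -> np.ndarray:
        ev = self.expected_values(params)
        cp = ChoiceParams(params["beta0"], params["beta1"])
        return np.asarray(buy_probability(ev, cp))

    def loglik(self, params: dict[str, float]) -> float:
        """Sum of log q over bought and log(1-q) over passed active trials."""
        if np.any(self._decision_arr[self._active_arr] < 0):
            raise IncompleteDataError(
                "dataset has active trials without recorded decisions"
            )
        q = self.buy_probabilities(params)
        mask = self._active_arr
        y = self._decision_arr[mask]
        qa = q[mask]
        return float(np.sum(np.where(y == 1, np.log(qa), np.log1p(-qa))))


def dataset_loglik(sessions, spec, params: dict[str, float],
                   alpha0: float = 1.0) -> float:
    """Log-likelihood of the active choices in ``sessions`` under a model.

    Replays each bin's draw stream through the model's learning rule,
    values each trial's gamble at the end of its stage, and scores the
    recorded buy/pass decisions with the softmax rule.
    """
    td = TrialData.from_sessions(sessions, spec, alpha0=alpha0)
    return td.loglik(params)
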