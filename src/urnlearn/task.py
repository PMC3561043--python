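"""Bin-sampling gamble task: design, simulation, and tabular serialization.

The task presents bins ("urns") of colored balls. Each color (a hidden
state) maps to a payoff displayed when a ball of that color is drawn.
A session runs 9 bins; each bin has two sampling stages. Within a stage,
10-14 balls are drawn with replacement and their payoffs shown, after which
the participant makes 6 priced buy/pass decisions on a gamble (an extra
draw from the same bin): 4 with the outcome unknown in advance (active) and
2 with it known (control). Between the two stages the color->payoff
assignment is re-randomized while the color probabilities stay fixed, so an
observer who tracks colors (hidden states) keeps its evidence across the
stage boundary whereas one who tracks payoffs must start over.

Payoffs are assigned to colors independently of the colors' probabilities,
which makes a state's probability orthogonal to its payoff magnitude by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientPayoffsError,
    InvalidDistributionError,
    InvalidStateCountError,
)

#: Default true state-probability vectors per state count. Skewed
#: distributions spanning low and high probabilities; the K=10 vector is a
#: normalized geometric decay with ratio 0.75.
DEFAULT_THETA: dict[int, tuple[float, ...]] = {
    2: (0.7, 0.3),
    5: (0.40, 0.25, 0.15, 0.12, 0.08),
    10: tuple(
        (0.75**i * (1 - 0.75) / (1 - 0.75**10)) for i in range(10)
    ),
}


@dataclass(frozen=True)
class TaskDesign:
    """Structural parameters of one simulated session.

    Defaults reproduce the study design: 9 bins (three each with 2, 5 and
    10 colors), 10-14 draws per stage, 6 priced choices per stage of which
    4 are active, integer payoffs drawn from [10, 99].
    """

    bins_per_session: int = 9
    state_counts: tuple[int, ...] = (2, 5, 10, 2, 5, 10, 2, 5, 10)
    draws_per_stage_range: tuple[int, int] = (10, 14)
    choices_per_stage: int = 6
    active_choices: int = 4
    payoff_pool: tuple[int, int] = (10, 99)
    #: optional per-bin pool widths cycled across bins, e.g. a narrow and a
    #: wide range to manipulate payoff spread independently of state count;
    #: None means every bin uses ``payoff_pool``
    payoff_pools: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.bins_per_session < 1:
            raise ValueError("bins_per_session must be >= 1")
        lo, hi = self.draws_per_stage_range
        if not (1 <= lo <= hi <= 100):
            raise ValueError("draws_per_stage_range must lie within [1, 100]")
        if self.active_choices > self.choices_per_stage:
            raise ValueError("active_choices cannot exceed choices_per_stage")
        if len(self.state_counts) != self.bins_per_session:
            raise ValueError("state_counts must list one K per bin")


@dataclass(frozen=True)
class BinConfig:
    """One bin: state count, true probabilities, per-stage payoff maps.

    ``payoffs`` has shape (2, K): row s-1 maps state k to its payoff in
    stage s. The two rows are drawn independently, emulating the
    re-randomization of the color->payoff legend at the resampling stage.
    """

    K: int
    theta: np.ndarray
    payoffs: np.ndarray  # shape (2, K), distinct within each row

    def payoff_map(self, stage: int) -> np.ndarray:
        if stage not in (1, 2):
            raise ValueError(f"stage must be 1 or 2, got {stage}")
        return self.payoffs[stage - 1]


@dataclass(frozen=True)
class DrawEvent:
    """One sampled ball: where it happened, what state, what payoff."""

    bin_id: int
    stage: int
    t: int  # 1-based draw index within the stage
    state: int
    payoff: float


@dataclass(frozen=True)
class ChoiceTrial:
    """One priced buy/pass decision at the end of a sampling stage."""

    bin_id: int
    stage: int
    choice_idx: int  # 1..choices_per_stage
    price: float
    condition: str  # "active" or "control"
    outcome_state: int
    outcome_payoff: float
    decision: int | None = None  # 1 = buy, 0 = pass, None = not yet made


@dataclass
class Session:
    """One subject's full task run."""

    subject: int
    bins: list[BinConfig]
    draws: list[DrawEvent]
    trials: list[ChoiceTrial]
    design: TaskDesign = field(default_factory=TaskDesign)


def _validate_theta(theta: np.ndarray) -> None:
    if np.any(theta <= 0) or np.any(theta >= 1):
        raise InvalidDistributionError("theta entries must lie in (0, 1)")
    if abs(theta.sum() - 1.0) > 1e-9:
        raise InvalidDistributionError(
            f"theta must sum to 1 (got {theta.sum():.12f})"
        )


def make_bin(
    K: int,
    theta: np.ndarray | None = None,
    payoff_pool: tuple[int, int] = (10, 99),
    rng: np.random.Generator | None = None,
) -> BinConfig:
    """Create a bin with theta permuted at random over states and two
    independently drawn payoff bijections.

    Permuting theta implements the random assignment of colors to
    probabilities at the start of each new bin; the independent payoff
    draws implement the per-stage re-assignment of payoffs to colors.
    """
    rng = np.random.default_rng() if rng is None else rng
    if K < 2:
        raise InvalidStateCountError(f"K must be >= 2, got {K}")
    if theta is None:
        if K not in DEFAULT_THETA:
            raise InvalidDistributionError(
                f"no default theta configured for K={K}; pass one explicitly"
            )
        theta = np.asarray(DEFAULT_THETA[K], dtype=float)
    else:
        theta = np.asarray(theta, dtype=float)
        if len(theta) != K:
            raise InvalidDistributionError("theta length must equal K")
    _validate_theta(theta)
    lo, hi = payoff_pool
    pool = np.arange(lo, hi + 1)
    if len(pool) < K:
        raise InsufficientPayoffsError(
            f"payoff pool [{lo}, {hi}] holds {len(pool)} values < K={K}"
        )
    theta = rng.permutation(theta)
    payoffs = np.stack(
        [rng.choice(pool, size=K, replace=False).astype(float) for _ in range(2)]
    )
    return BinConfig(K=K, theta=theta, payoffs=payoffs)


def sample_draws(
    bin_config: BinConfig,
    stage: int,
    n_draws: int,
    rng: np.random.Generator,
    bin_id: int = 0,
) -> list[DrawEvent]:
    """Draw ``n_draws`` balls with replacement from the bin."""
    pmap = bin_config.payoff_map(stage)
    states = rng.choice(bin_config.K, size=n_draws, p=bin_config.theta)
    return [
        DrawEvent(bin_id=bin_id, stage=stage, t=t + 1, state=int(k),
                  payoff=float(pmap[k]))
        for t, k in enumerate(states)
    ]


def make_prices(
    bin_config: BinConfig, stage: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` prices uniformly between the stage's min and max payoff."""
    pmap = bin_config.payoff_map(stage)
    return rng.uniform(pmap.min(), pmap.max(), size=n)


def simulate_session(
    design: TaskDesign,
    rng: np.random.Generator,
    subject: int = 0,
) -> Session:
    """Simulate one subject's session; choice trials carry no decisions yet.

    Bin order follows ``design.state_counts``. Each choice trial's realized
    outcome is an independent extra draw from the bin, made at generation
    time so that active and control trials differ only in whether the
    outcome is revealed before the decision.
    """
    lo, hi = design.draws_per_stage_range
    bins: list[BinConfig] = []
    draws: list[DrawEvent] = []
    trials: list[ChoiceTrial] = []
    for bin_id, K in enumerate(design.state_counts):
        pool = (
            design.payoff_pools[bin_id % len(design.payoff_pools)]
            if design.payoff_pools
            else design.payoff_pool
        )
        bc = make_bin(K, payoff_pool=pool, rng=rng)
        bins.append(bc)
        for stage in (1, 2):
            n_draws = int(rng.integers(lo, hi + 1))
            draws.extend(sample_draws(bc, stage, n_draws, rng, bin_id=bin_id))
            conditions = ["active"] * design.active_choices + ["control"] * (
                design.choices_per_stage - design.active_choices
            )
            conditions = list(rng.permutation(conditions))
            prices = make_prices(bc, stage, design.choices_per_stage, rng)
            pmap = bc.payoff_map(stage)
            for idx in range(design.choices_per_stage):
                k = int(rng.choice(bc.K, p=bc.theta))
                trials.append(
                    ChoiceTrial(
                        bin_id=bin_id,
                        stage=stage,
                        choice_idx=idx + 1,
                        price=float(prices[idx]),
                        condition=conditions[idx],
                        outcome_state=k,
                        outcome_payoff=float(pmap[k]),
                    )
                )
    return Session(subject=subject, bins=bins, draws=draws, trials=trials,
                   design=design)


def simulate_choices(
    session: Session,
    spec,
    params: dict[str, float],
    rng: np.random.Generator,
) -> Session:
    """Fill in buy/pass decisions sampled from a choice model.

    Each trial's buy probability comes from the softmax (logistic) rule
    applied to the model's end-of-stage gamble valuation; the decision is a
    Bernoulli draw from it. Control trials are simulated the same way (the
    model sees the same information) but are excluded from fitting.
    """
    from .choice import TrialData, check_params

    check_params(spec, params)
    td = TrialData.from_sessions([session], spec, include_control=True)
    q = td.buy_probabilities(params)
    u = rng.random(len(q))
    decisions = (u < q).astype(int)
    new_trials = [
        replace(trial, decision=int(d))
        for trial, d in zip(td.trials_in_order(session), decisions)
    ]
    return replace_session_trials(session, new_trials)


def replace_session_trials(session: Session, trials: list[ChoiceTrial]) -> Session:
    return Session(
        subject=session.subject,
        bins=session.bins,
        draws=session.draws,
        trials=trials,
        design=session.design,
    )


def simulate_cohort(
    design: TaskDesign,
    n_subjects: int,
    spec,
    params: dict[str, float],
    seed: int | np.random.SeedSequence,
) -> list[Session]:
    """Simulate a cohort with per-subject substreams spawned from one seed."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    sessions = []
    for subject, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        sess = simulate_session(design, rng, subject=subject)
        sessions.append(simulate_choices(sess, spec, params, rng))
    return sessions


# ---------------------------------------------------------------------------
# Tabular serialization (TSV, "." decimal, UTF-8)

def sessions_to_frames(sessions: list[Session]) -> dict[str, pd.DataFrame]:
    """Flatten sessions into draws/choices/bins tables.

    The bins table carries the true probabilities and both stages' payoff
    maps; without it the payoff of a never-drawn state could not be
    recovered from the draw stream.
    """
    draw_rows, choice_rows, bin_rows = [], [], []
    for sess in sessions:
        s = sess.subject
        for d in sess.draws:
            draw_rows.append(
                (s, d.bin_id, d.stage, d.t, d.state, d.payoff)
            )
        for c in sess.trials:
            choice_rows.append(
                (s, c.bin_id, c.stage, c.choice_idx, c.price, c.condition,
                 -1 if c.decision is None else c.decision,
                 c.outcome_state, c.outcome_payoff)
            )
        for bin_id, bc in enumerate(sess.bins):
            for k in range(bc.K):
                bin_rows.append(
                    (s, bin_id, bc.K, k, bc.theta[k],
                     bc.payoffs[0, k], bc.payoffs[1, k])
                )
    draws = pd.DataFrame(
        draw_rows, columns=["subject", "bin", "stage", "t", "state", "payoff"]
    )
    choices = pd.DataFrame(
        choice_rows,
        columns=["subject", "bin", "stage", "choice_idx", "price",
                 "condition", "decision", "outcome_state", "outcome_payoff"],
    )
    bins = pd.DataFrame(
        bin_rows,
        columns=["subject", "bin", "K", "state", "theta",
                 "payoff_stage1", "payoff_stage2"],
    )
    return {"draws": draws, "choices": choices, "bins": bins}


def frames_to_sessions(frames: dict[str, pd.DataFrame]) -> list[Session]:
    """Rebuild Session objects from the three tables."""
    draws_df, choices_df, bins_df = (
        frames["draws"], frames["choices"], frames["bins"]
    )
    sessions = []
    for subject in sorted(bins_df["subject"].unique()):
        bsub = bins_df[bins_df["subject"] == subject]
        bins = []
        for bin_id in sorted(bsub["bin"].unique()):
            rows = bsub[bsub["bin"] == bin_id].sort_values("state")
            bins.append(
                BinConfig(
                    K=int(rows["K"].iloc[0]),
                    theta=rows["theta"].to_numpy(float),
                    payoffs=np.stack(
                        [rows["payoff_stage1"].to_numpy(float),
                         rows["payoff_stage2"].to_numpy(float)]
                    ),
                )
            )
        dsub = draws_df[draws_df["subject"] == subject]
        draws = [
            DrawEvent(int(r.bin), int(r.stage), int(r.t), int(r.state),
                      float(r.payoff))
            for r in dsub.itertuples()
        ]
        csub = choices_df[choices_df["subject"] == subject]
        trials = [
            ChoiceTrial(
                int(r.bin), int(r.stage), int(r.choice_idx), float(r.price),
                str(r.condition),
                int(r.outcome_state), float(r.outcome_payoff),
                None if int(r.decision) < 0 else int(r.decision),
            )
            for r in csub.itertuples()
        ]
        sessions.append(
            Session(subject=int(subject), bins=bins, draws=draws,
                    trials=trials)
        )
    return sessions


def write_sessions(sessions: list[Session], out_dir) -> None:
    """Write draws.tsv, choices.tsv, bins.tsv under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in sessions_to_frames(sessions).items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                  encoding="utf-8")


def read_sessions(in_dir) -> list[Session]:
    from pathlib import Path

    src = Path(in_dir)
    frames = {
        name: pd.read_csv(src / f"{name}.tsv", sep="\t",
                          float_precision="round_trip")
        for name in ("draws", "choices", "bins")
    }
    return frames_to_sessions(frames)
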