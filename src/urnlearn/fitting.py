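"""Maximum-likelihood fitting, BIC model comparison, and recovery studies.

Each model's likelihood is maximized with Nelder-Mead in an unconstrained
space reached through per-parameter transforms (log for the positive
loss-aversion and sensitivity parameters, scaled logit for the bounded
weighting curvature and learning rate, identity for the logistic intercept
and slope). The search restarts from several random starting points and
keeps the best; on well-sized data the restarts land within a hair of one
another, and the spread is reported so that flat or multi-modal likelihoods
are visible. Models are compared with the Bayesian information criterion
BIC = -2 * MLL + n_params * ln(n_data); lower is better, and ties break
toward the model with fewer parameters.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .choice import MODEL_SPECS, ModelSpec, TrialData, get_spec
from .exceptions import FitFailureError, IncompleteDataError
from .task import TaskDesign, simulate_cohort

#: Table-style default generating parameters per model tag, used by the
#: recovery studies when no explicit values are supplied.
DEFAULT_GENERATING_PARAMS: dict[str, dict[str, float]] = {
    "M2": {"beta0": -0.49, "beta1": 0.38},
    "M3": {"beta0": -0.39, "beta1": 0.31, "eta": 0.17},
    "M4": {"beta0": 0.95, "beta1": 0.54, "lam": 2.57, "alpha": 0.69},
    "M4a": {"beta0": 1.00, "beta1": 0.53, "lam": 2.66, "alpha": 0.68},
    "M4b": {"beta0": 0.51, "beta1": 1.31, "lam": 1.69, "alpha": 0.44},
    "M5": {"beta0": 1.00, "beta1": 0.59, "lam": 2.55, "alpha": 0.63,
           "gamma": 0.89},
}

_GAMMA_BOUNDS = (0.3, 2.0)


def _to_unconstrained(name: str, value: float) -> float:
    if name in ("lam", "alpha"):
        return math.log(value)
    if name == "gamma":
        lo, hi = _GAMMA_BOUNDS
        return float(logit((value - lo) / (hi - lo)))
    if name == "eta":
        return float(logit(min(max(value, 1e-9), 1 - 1e-9)))
    return value


def _from_unconstrained(name: str, value: float) -> float:
    if name in ("lam", "alpha"):
        return math.exp(value)
    if name == "gamma":
        lo, hi = _GAMMA_BOUNDS
        return lo + (hi - lo) * float(expit(value))
    if name == "eta":
        return float(expit(value))
    return value


#: Starting-point distributions for the restart draws.
def _draw_start(spec: ModelSpec, rng: np.random.Generator) -> dict[str, float]:
    draw = {
        "beta0": rng.normal(0.0, 1.0),
        "beta1": rng.uniform(0.1, 2.0),
        "lam": rng.uniform(0.5, 3.0),
        "alpha": rng.uniform(0.3, 1.2),
        "gamma": rng.uniform(0.5, 1.5),
        "eta": rng.uniform(0.1, 0.9),
    }
    return {name: draw[name] for name in spec.param_names}


def bic(mll: float, n_params: int, n_data: int) -> float:
    """Bayesian information criterion; lower is better."""
    if n_data < 1:
        raise ValueError("n_data must be >= 1")
    return -2.0 * mll + n_params * math.log(n_data)


@dataclass
class FitResult:
    """Outcome of one model fit."""

    tag: str
    estimates: dict[str, float]
    mll: float
    bic: float
    n_data: int
    restart_mlls: list[float]
    converged: bool
    seed: int | None = None

    @property
    def restart_spread(self) -> float:
        finite = [m for m in self.restart_mlls if math.isfinite(m)]
        return max(finite) - min(finite) if len(finite) > 1 else 0.0


def _as_trialdata(dataset, spec: ModelSpec, alpha0: float) -> TrialData:
    if isinstance(dataset, TrialData):
        return dataset
    return TrialData.from_sessions(dataset, spec, alpha0=alpha0)


def fit_model(
    dataset,
    spec,
    n_restarts: int = 5,
    rng: np.random.Generator | int | None = None,
    alpha0: float = 1.0,
    xatol: float = 1e-8,
    fatol: float = 1e-8,
    maxiter: int = 5000,
) -> FitResult:
    """Maximize the dataset log-likelihood under one model.

    ``dataset`` is a list of sessions or a pre-built :class:`TrialData`.
    The best of ``n_restarts`` Nelder-Mead runs is retained.
    """
    spec = get_spec(spec)
    td = _as_trialdata(dataset, spec, alpha0)
    if td.n_active < 10 * spec.n_params:
        raise IncompleteDataError(
            f"{td.n_active} active choices is too few to identify "
            f"{spec.n_params} parameters (need >= {10 * spec.n_params})"
        )
    rng = np.random.default_rng(rng)
    names = spec.param_names

    def neg_ll(z: np.ndarray) -> float:
        params = {n: _from_unconstrained(n, v) for n, v in zip(names, z)}
        try:
            return -td.loglik(params)
        except (OverflowError, FloatingPointError):
            return np.inf

    best = None
    restart_mlls: list[float] = []
    for _ in range(n_restarts):
        start = _draw_start(spec, rng)
        z0 = np.array([_to_unconstrained(n, start[n]) for n in names])
        res = minimize(
            neg_ll, z0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
        )
        restart_mlls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun):
        raise FitFailureError(f"likelihood non-finite at every start ({spec.tag})")
    estimates = {
        n: _from_unconstrained(n, v) for n, v in zip(names, best.x)
    }
    mll = -float(best.fun)
    return FitResult(
        tag=spec.tag,
        estimates=estimates,
        mll=mll,
        bic=bic(mll, spec.n_params, td.n_active),
        n_data=td.n_active,
        restart_mlls=restart_mlls,
        converged=bool(best.success),
    )


def compare_models(
    dataset,
    specs,
    n_restarts: int = 5,
    seed: int = 0,
    alpha0: float = 1.0,
) -> pd.DataFrame:
    """Fit each model and tabulate estimates, MLL and BIC.

    The minimum-BIC model is flagged in the ``best`` column; BIC ties
    break toward fewer parameters. Each model's restart stream is derived
    from ``(seed, tag)``, so identical specs produce identical rows.
    """
    specs = [get_spec(s) for s in specs]
    if len(specs) < 2:
        raise ValueError("compare_models needs at least two model specs")
    rows = []
    for spec in specs:
        rng = np.random.default_rng(
            [seed, zlib.crc32(spec.tag.encode())]
        )
        fit = fit_model(dataset, spec, n_restarts=n_restarts, rng=rng,
                        alpha0=alpha0)
        row = {"model": spec.tag, "n_params": spec.n_params,
               "mll": fit.mll, "bic": fit.bic, "n_data": fit.n_data,
               "restart_spread": fit.restart_spread}
        row.update(fit.estimates)
        rows.append(row)
    table = pd.DataFrame(rows)
    order = np.lexsort((table["n_params"].to_numpy(),
                        table["bic"].to_numpy()))
    best_idx = order[0]
    table["best"] = [i == best_idx for i in range(len(table))]
    return table


def select_model(table: pd.DataFrame) -> str:
    return str(table.loc[table["best"], "model"].iloc[0])


@dataclass
class RecoveryReport:
    """Result of a parameter- or model-recovery simulation."""

    generating: dict
    replicates: pd.DataFrame
    bias: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)
    confusion: pd.DataFrame | None = None


def parameter_recovery(
    spec,
    generating_params: dict[str, float] | None = None,
    n_subjects: int = 23,
    replicates: int = 50,
    seed: int = 0,
    design: TaskDesign | None = None,
    n_restarts: int = 5,
) -> RecoveryReport:
    """Simulate cohorts from a model and refit it; report bias and RMSE."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec = get_spec(spec)
    params = generating_params or DEFAULT_GENERATING_PARAMS[spec.tag]
    design = design or TaskDesign()
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(root.spawn(replicates)):
        sim_ss, fit_ss = child.spawn(2)
        sessions = simulate_cohort(design, n_subjects, spec, params, sim_ss)
        fit = fit_model(sessions, spec, n_restarts=n_restarts,
                        rng=np.random.default_rng(fit_ss))
        row = {"replicate": rep, "mll": fit.mll, "bic": fit.bic}
        row.update(fit.estimates)
        rows.append(row)
    reps = pd.DataFrame(rows)
    bias = {n: float(reps[n].mean() - params[n]) for n in spec.param_names}
    rmse = {
        n: float(np.sqrt(((reps[n] - params[n]) ** 2).mean()))
        for n in spec.param_names
    }
    return RecoveryReport(
        generating={"spec": spec.tag, "params": dict(params),
                    "n_subjects": n_subjects, "seed": seed},
        replicates=reps, bias=bias, rmse=rmse,
    )


def model_recovery(
    specs,
    generating_params_per_spec: dict[str, dict[str, float]] | None = None,
    replicates: int = 10,
    n_subjects: int = 23,
    seed: int = 0,
    design: TaskDesign | None = None,
    fit_specs=None,
    n_restarts: int = 5,
) -> RecoveryReport:
    """Confusion matrix of BIC-selected versus generating model."""
    if replicates < 10:
        raise ValueError("replicates must be >= 10 for a stable confusion matrix")
    specs = [get_spec(s) for s in specs]
    fit_specs = [get_spec(s) for s in (fit_specs or specs)]
    gen_params = generating_params_per_spec or {
        s.tag: DEFAULT_GENERATING_PARAMS[s.tag] for s in specs
    }
    design = design or TaskDesign()
    root = np.random.SeedSequence(seed)
    tags = [s.tag for s in fit_specs]
    confusion = pd.DataFrame(0, index=[s.tag for s in specs], columns=tags)
    rows = []
    for gen_spec in specs:
        params = gen_params[gen_spec.tag]
        for rep, child in enumerate(root.spawn(replicates)):
            sim_ss, fit_ss = child.spawn(2)
            sessions = simulate_cohort(design, n_subjects, gen_spec, params,
                                       sim_ss)
            table = compare_models(
                sessions, fit_specs, n_restarts=n_restarts,
                seed=int(fit_ss.generate_state(1)[0]),
            )
            selected = select_model(table)
            confusion.loc[gen_spec.tag, selected] += 1
            for _, r in table.iterrows():
                rows.append({"generating": gen_spec.tag, "replicate": rep,
                             "model": r["model"], "bic": r["bic"],
                             "mll": r["mll"]})
    return RecoveryReport(
        generating={"specs": [s.tag for s in specs], "params": gen_params,
                    "n_subjects": n_subjects, "seed": seed},
        replicates=pd.DataFrame(rows),
        confusion=confusion,
    )
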