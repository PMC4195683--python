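"""Weighted least-squares fitting of model parameters to sparse observations.

Individual patients are characterized by refitting only the parameters the
sensitivity analysis marks as sensitive (see :mod:`sixmp.gsa`); everything
else stays at the average-patient value.  The cost is the weighted sum of
squared errors between simulated outputs and clinical measurements; the
optimizer is a hybrid of a seeded evolutionary global stage
(``scipy.optimize.differential_evolution``, evaluated in batch through the
fast engine) and a bounded local refinement.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from . import _fast
from .errors import DomainError, InsufficientDataError, NoFeasibleCandidateError
from .params import ErythroParams, LeukoParams, Patient, SixMPParams, _locate_param
from .simulate import DoseRegimen

log = logging.getLogger(__name__)

#: Observable variables and the model systems they require.
OBSERVABLE_SYSTEMS = {"x_t": "pk", "x_m": "pk", "L": "leuko", "dmcv": "erythro"}


@dataclass(frozen=True)
class ObservationSet:
    """Sparse clinical measurements: (time_days, variable, value[, weight]).

    Variables are ``x_t`` (RBC 6-TGN), ``x_m`` (MeMP), ``L`` (leukocytes)
    and ``dmcv`` (MCV change from untreated baseline).  Missing weights
    default to the variable-level normalization 1/mean(observed)^2, making
    multi-variable costs dimensionless.
    """

    frame: pd.DataFrame
    label: str = ""

    def __post_init__(self):
        frame = self.frame.copy()
        required = {"time_days", "variable", "value"}
        if not required.issubset(frame.columns):
            raise DomainError(f"observations need columns {sorted(required)}")
        unknown = set(frame["variable"]) - set(OBSERVABLE_SYSTEMS)
        if unknown:
            raise DomainError(f"unknown observed variables: {sorted(unknown)}")
        if not np.isfinite(frame["value"]).all():
            raise DomainError("observation values must be finite")
        if "weight" not in frame.columns:
            frame["weight"] = np.nan
        if (frame["weight"].dropna() <= 0).any():
            raise DomainError("observation weights must be positive")
        frame = frame.sort_values(["time_days", "variable"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    @classmethod
    def from_records(cls, records, label: str = "") -> "ObservationSet":
        frame = pd.DataFrame(records, columns=["time_days", "variable", "value", "weight"][: len(records[0])])
        return cls(frame=frame, label=label)

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "ObservationSet":
        return cls(frame=pd.read_csv(path), label=label if label is not None else str(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, lineterminator="\n")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def variables(self) -> tuple:
        return tuple(dict.fromkeys(self.frame["variable"]))

    def effective_weights(self) -> np.ndarray:
        """Per-record weights with defaults 1/mean(|observed|)^2 per variable."""
        w = self.frame["weight"].to_numpy(dtype=float).copy()
        for var in self.variables:
            mask = (self.frame["variable"] == var).to_numpy()
            if np.isnan(w[mask]).any():
                mean = np.mean(np.abs(self.frame.loc[mask, "value"]))
                default = 1.0 / mean**2 if mean > 0 else 1.0
                w[mask] = np.where(np.isnan(w[mask]), default, w[mask])
        return w

    def earliest_fraction(self, fraction: float) -> tuple["ObservationSet", "ObservationSet"]:
        """Chronological split: the earliest ceil(fraction*n) records, and the rest."""
        n_train = math.ceil(fraction * len(self))
        train = self.frame.iloc[:n_train]
        test = self.frame.iloc[n_train:]
        return (ObservationSet(train, label=f"{self.label}/train"),
                ObservationSet(test, label=f"{self.label}/holdout"))


@dataclass(frozen=True)
class SimConfig:
    """How to simulate when evaluating a candidate parameter set."""

    regimen: DoseRegimen
    base: Patient = field(default_factory=Patient)
    horizon_days: float | None = None
    dt_pk: float = _fast.DEFAULT_DT_PK
    dt_pd: float = _fast.DEFAULT_DT_PD


@dataclass(frozen=True)
class FitSpec:
    """Free parameters, bounds, and optimizer budget for one fit."""

    free: tuple
    bounds: dict
    seed: int
    fixed: dict = field(default_factory=dict)
    population: int = 50
    generations: int = 100
    local_iters: int = 500

    def __post_init__(self):
        object.__setattr__(self, "free", tuple(self.free))
        for name in self.free:
            _locate_param(name)  # raises on unknown names
            lo, hi = self.bounds[name]
            if lo > hi:
                raise DomainError(f"bounds for {name} have lower > upper")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a hybrid global+local fit."""

    estimates: dict
    cost: float
    per_variable_sse: dict
    n_evaluations: int
    seed: int
    global_cost: float
    message: str = ""

    def as_patient(self, base: Patient, id: str | None = None) -> Patient:
        return base.with_overrides(self.estimates, id=id)


class _BatchCost:
    """Vectorized weighted-SSE evaluator over candidate parameter matrices."""

    def __init__(self, obs: ObservationSet, config: SimConfig, free: tuple, fixed: dict | None = None):
        self.obs = obs
        self.config = config
        self.free = tuple(free)
        self.base = config.base.with_overrides(dict(fixed or {}))
        self.weights = obs.effective_weights()
        self.times = obs.frame["time_days"].to_numpy(dtype=float)
        self.values = obs.frame["value"].to_numpy(dtype=float)
        self.var_masks = {v: (obs.frame["variable"] == v).to_numpy() for v in obs.variables}
        systems = {OBSERVABLE_SYSTEMS[v] for v in obs.variables}
        self.need_leuko = "leuko" in systems
        self.need_erythro = "erythro" in systems
        horizon = config.horizon_days
        if horizon is None:
            horizon = max(self.times.max() if self.times.size else 0.0,
                          config.regimen.max_time + 1.0)
        self.horizon = float(horizon)
        self.grid = _fast.uniform_grid(self.horizon, config.dt_pk)
        self.ev_t, self.ev_pmol = config.regimen.arrays_pmol()
        self.n_evaluations = 0

    def _param_arrays(self, theta: np.ndarray, cls, base_params) -> dict:
        out = {}
        for name in cls.field_names():
            if name in self.free:
                out[name] = theta[:, self.free.index(name)]
            else:
                out[name] = np.full(theta.shape[0], getattr(base_params, name))
        return out

    def predict(self, theta: np.ndarray) -> dict:
        """Predicted observables at observation times; arrays (S, n_obs)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        S = theta.shape[0]
        pk = self._param_arrays(theta, SixMPParams, self.base.pk)
        pkc = _fast.pk_curves(pk, self.ev_t, self.ev_pmol, self.grid)
        dt = self.grid[1] - self.grid[0]
        preds = {}
        if "x_t" in self.var_masks:
            preds["x_t"] = _fast.resample_uniform(pkc["x_t"], 0.0, dt, self.times[self.var_masks["x_t"]])
        if "x_m" in self.var_masks:
            preds["x_m"] = _fast.resample_uniform(pkc["x_m"], 0.0, dt, self.times[self.var_masks["x_m"]])

        if self.need_leuko or self.need_erythro:
            n_pd = max(1, int(round(self.horizon / self.config.dt_pd)))
            dt_pd = self.horizon / n_pd
            half_times = np.arange(2 * n_pd + 1) * (dt_pd / 2.0)
            xt_half = _fast.resample_uniform(pkc["x_t"], 0.0, dt, half_times)
            if xt_half.shape[0] == 1 and S > 1:
                xt_half = np.broadcast_to(xt_half, (S, xt_half.shape[1]))
        if self.need_leuko:
            lp = self._param_arrays(theta, LeukoParams, self.base.leuko)
            y0, feasible_l = _leuko_baseline_batch(lp, S)
            traj = _fast.pd_curves("leuko", lp, xt_half, dt_pd, y0)
            pred = _fast.resample_uniform(traj[:, :, 4], 0.0, dt_pd, self.times[self.var_masks["L"]])
            pred[~feasible_l] = np.nan
            preds["L"] = pred
        if self.need_erythro:
            ep = self._param_arrays(theta, ErythroParams, self.base.erythro)
            y0, feasible_e = _erythro_baseline_batch(ep, S)
            traj = _fast.pd_curves("erythro", ep, xt_half, dt_pd, y0)
            m = _fast.resample_uniform(traj[:, :, 5], 0.0, dt_pd, self.times[self.var_masks["dmcv"]])
            pred = m - np.broadcast_to(ep["M_in"], (S,))[:, None]
            pred[~feasible_e] = np.nan
            preds["dmcv"] = pred
        return preds

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        self.n_evaluations += theta.shape[0]
        preds = self.predict(theta)
        cost = np.zeros(theta.shape[0])
        for var, mask in self.var_masks.items():
            resid = preds[var] - self.values[mask][None, :]
            cost += np.sum(self.weights[mask][None, :] * resid**2, axis=1)
        bad = ~np.isfinite(cost)
        if bad.any():
            log.warning("simulation failure for %d/%d candidates; cost set to +inf",
                        int(bad.sum()), theta.shape[0])
            cost[bad] = np.inf
        return cost

    def scalar(self, theta_vec) -> float:
        return float(self(np.atleast_2d(theta_vec))[0])

    def per_variable_sse(self, theta_vec) -> dict:
        preds = self.predict(np.atleast_2d(theta_vec))
        out = {}
        for var, mask in self.var_masks.items():
            resid = preds[var][0] - self.values[mask]
            out[var] = float(np.sum(self.weights[mask] * resid**2))
        return out


def _leuko_baseline_batch(lp: dict, S: int):
    demand = lp["k_tl"] + lp["k_sl"]
    feasible = lp["k_pl"] > demand
    with np.errstate(invalid="ignore", divide="ignore"):
        L_eq = lp["theta_L"] * ((lp["k_pl"] - demand) / demand) ** (1.0 / lp["s_l"])
        chain = lp["k_dl"] * L_eq / (lp["kappa"] * lp["k_tl"])
    y0 = np.empty((S, 5))
    for j in range(4):
        y0[:, j] = chain
    y0[:, 4] = L_eq
    y0[~np.broadcast_to(feasible, (S,))] = 1.0  # placeholder; cost becomes +inf via nan preds
    return y0, np.broadcast_to(feasible, (S,)).copy()


def _erythro_baseline_batch(ep: dict, S: int):
    demand = ep["k_tr"] + ep["k_sr"]
    feasible = ep["k_pr"] > demand
    with np.errstate(invalid="ignore", divide="ignore"):
        R_eq = ep["theta_R"] * ((ep["k_pr"] - demand) / demand) ** (1.0 / ep["s_r"])
        chain = ep["k_dr"] * R_eq / ep["k_tr"]
    y0 = np.empty((S, 6))
    for j in range(4):
        y0[:, j] = chain
    y0[:, 4] = R_eq
    y0[:, 5] = ep["M_in"]
    y0[~np.broadcast_to(feasible, (S,))] = 1.0
    return y0, np.broadcast_to(feasible, (S,)).copy()


def weighted_sse(candidate_params: dict, obs: ObservationSet, sim_config: SimConfig) -> float:
    """Weighted sum of squared errors of a named-parameter candidate.

    ``candidate_params`` maps parameter names to values; unnamed parameters
    come from ``sim_config.base``.  Simulation failure yields ``+inf`` (the
    optimizer-safe convention) with a logged diagnostic.
    """
    names = tuple(candidate_params)
    evaluator = _BatchCost(obs, sim_config, free=names)
    theta = np.array([[candidate_params[n] for n in names]])
    return float(evaluator(theta)[0])


def fit_parameters(obs: ObservationSet, spec: FitSpec, sim_config: SimConfig) -> FitResult:
    """Hybrid global (seeded differential evolution) + local bounded fit.

    Deterministic given ``spec.seed``; the returned cost never exceeds the
    best cost seen in the global stage.  Bounds collapsed to a point pin the
    parameter at that value.
    """
    pinned = {n: spec.bounds[n][0] for n in spec.free if spec.bounds[n][0] == spec.bounds[n][1]}
    free = tuple(n for n in spec.free if n not in pinned)
    fixed = {**spec.fixed, **pinned}
    evaluator = _BatchCost(obs, sim_config, free=free, fixed=fixed)

    if not free:
        theta = np.zeros((1, 0))
        cost = float(evaluator(theta)[0])
        return FitResult(estimates=dict(pinned), cost=cost,
                         per_variable_sse=evaluator.per_variable_sse(theta[0]),
                         n_evaluations=1, seed=spec.seed, global_cost=cost,
                         message="all bounds collapsed; returned the pinned point")

    bounds = [tuple(map(float, spec.bounds[n])) for n in free]
    d = len(free)
    popsize = max(5, round(spec.population / d))

    def vec_obj(x):
        # scipy passes (d,) in scalar mode and (d, S) in vectorized mode
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return evaluator.scalar(x)
        return evaluator(x.T)

    result = differential_evolution(
        vec_obj, bounds, seed=spec.seed, maxiter=spec.generations, popsize=popsize,
        init="sobol", tol=1e-10, polish=False, vectorized=True, updating="deferred",
    )
    x_best, global_cost = np.asarray(result.x, dtype=float), float(result.fun)
    if not np.isfinite(global_cost):
        raise NoFeasibleCandidateError("no feasible candidate found within the optimizer budget")

    local = minimize(evaluator.scalar, x_best, method="L-BFGS-B", bounds=bounds,
                     options={"maxfun": spec.local_iters})
    if np.isfinite(local.fun) and local.fun <= global_cost:
        x_best, cost = np.clip(local.x, [b[0] for b in bounds], [b[1] for b in bounds]), float(local.fun)
    else:
        cost = global_cost

    estimates = {**pinned, **{n: float(v) for n, v in zip(free, x_best)}}
    return FitResult(
        estimates=estimates, cost=cost,
        per_variable_sse=evaluator.per_variable_sse(x_best),
        n_evaluations=evaluator.n_evaluations, seed=spec.seed, global_cost=global_cost,
        message=str(getattr(local, "message", "")),
    )


def default_bounds(names, base: Patient, factor: tuple = (0.5, 2.0)) -> dict:
    """Feasible-range bounds as multiples of the average-patient value."""
    return {n: (factor[0] * base.get_param(n), factor[1] * base.get_param(n)) for n in names}


def individualize(
    obs: ObservationSet,
    sensitive_names,
    average: Patient,
    sim_config: SimConfig | None = None,
    seed: int = 0,
    bounds: dict | None = None,
    id: str | None = None,
    **budget,
) -> tuple[Patient, FitResult | None]:
    """Refit only the sensitive parameters; freeze the rest at average values.

    Returns the individualized patient and the fit result (``None`` when the
    sensitive set or the observation set is empty, in which case the average
    patient is returned unchanged with a warning).
    """
    sensitive_names = tuple(sensitive_names)
    if not sensitive_names or len(obs) == 0:
        warnings.warn("empty sensitive set or no observations; returning the average patient",
                      stacklevel=2)
        return average, None
    if sim_config is None:
        raise DomainError("individualize requires a SimConfig")
    sim_config = replace(sim_config, base=average)
    spec = FitSpec(free=sensitive_names,
                   bounds=bounds or default_bounds(sensitive_names, average),
                   seed=seed, **budget)
    result = fit_parameters(obs, spec, sim_config)
    return result.as_patient(average, id=id), result


@dataclass(frozen=True)
class HoldoutResult:
    sse_full: float
    sse_train_predict: float
    relative_gap: float
    n_train: int
    n_total: int


def holdout_validate(
    obs: ObservationSet,
    spec: FitSpec,
    sim_config: SimConfig,
    train_fraction: float = 2.0 / 3.0,
) -> HoldoutResult:
    """Forward-in-time predictive check of an individualized fit.

    Fits on the earliest ``ceil(train_fraction * n)`` records and on the full
    set; both fits are scored on all records (full-set default weights) and
    the relative SSE gap |SSE_train_fit - SSE_full_fit| / SSE_full_fit is
    reported.
    """
    counts = obs.frame["variable"].value_counts()
    if (counts < 3).any() or len(obs) < 3:
        raise InsufficientDataError("need at least 3 records per fitted variable for a holdout split")
    train, _ = obs.earliest_fraction(train_fraction)

    # pin full-set weights so both fits score on the identical cost surface
    full_frame = obs.frame.copy()
    full_frame["weight"] = obs.effective_weights()
    obs_weighted = ObservationSet(full_frame, label=obs.label)
    train_frame = train.frame.copy()
    train_frame["weight"] = full_frame["weight"].iloc[: len(train_frame)].to_numpy()
    train_weighted = ObservationSet(train_frame, label=train.label)

    fit_full = fit_parameters(obs_weighted, spec, sim_config)
    fit_train = fit_parameters(train_weighted, spec, sim_config)

    sse_full = weighted_sse(fit_full.estimates, obs_weighted, sim_config)
    sse_train_predict = weighted_sse(fit_train.estimates, obs_weighted, sim_config)
    # floor the denominator at the interpolation-noise scale (an SSE below
    # ~1e-5 of the weighted data scale is a noise-free fit converged to
    # optimizer tolerance) so such fits report a vanishing gap, not 0/0
    scale = float(np.sum(obs_weighted.effective_weights() * obs_weighted.frame["value"] ** 2))
    denom = max(sse_full, 1e-5 * scale)
    gap = abs(sse_train_predict - sse_full) / denom if denom > 0 else 0.0
    return HoldoutResult(sse_full=sse_full, sse_train_predict=sse_train_predict,
                         relative_gap=gap, n_train=len(train_weighted), n_total=len(obs))
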