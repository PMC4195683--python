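"""Variance-based global sensitivity analysis and model reduction.

Total Sobol indices are estimated with the Saltelli paired-matrix design
(low-discrepancy Sobol' sequence, uniform marginals over a
[0.5, 2.0] x nominal hyper-box) and Jansen's total-effect formula.  Each
parameter's total index at a set of representative time points is converted
into a probabilistic *freezing error* — a confidence bound on the output
error incurred by fixing the parameter at its nominal value — and parameters
whose cumulative freezing error falls below 5% of the largest are declared
redundant: they are frozen at the average-patient value for every patient,
and only the remaining sensitive parameters are individualized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import _fast
from .errors import ConfigError, DomainError
from .params import Patient
from .simulate import DoseRegimen

#: Parameters scanned per model output (the full parameter set of the model
#: that produces the output).
GSA_PARAMETERS = {
    "x_t": ("k_a", "k_e", "k_pt", "K_t", "k_pm", "K_m", "k_te", "k_me"),
    "L": ("k_pl", "theta_L", "s_l", "k_tl", "k_sl", "k_dl", "EL_max", "ECL_50", "h_l"),
    "M": ("k_pr", "theta_R", "s_r", "k_tr", "k_sr", "k_dr", "ER_max", "ECR_50", "h_r", "M_in", "k_m6"),
}


@dataclass(frozen=True)
class GsaSpec:
    """Design of one sensitivity run on a clinically measurable output."""

    output: str = "x_t"
    nominal: dict = field(default_factory=dict)   # name -> nominal value
    bounds_factor: tuple = (0.5, 2.0)
    n: int = 1000
    time_points: tuple = ()
    p: float = 0.05
    threshold: float = 0.05
    seed: int = 0
    regimen: DoseRegimen = field(default_factory=lambda: DoseRegimen.daily(75, 112))
    horizon_days: float = 112.0

    def __post_init__(self):
        if self.output not in GSA_PARAMETERS:
            raise ConfigError(f"output must be one of {sorted(GSA_PARAMETERS)}")
        if not (0.0 < self.p < 1.0):
            raise ConfigError("probability level p must lie in (0, 1)")
        if self.n < 64:
            raise ConfigError("need at least 64 base samples")
        nominal = dict(self.nominal)
        if not nominal:
            base = Patient()
            nominal = {name: base.get_param(name) for name in GSA_PARAMETERS[self.output]}
        object.__setattr__(self, "nominal", nominal)
        tp = tuple(self.time_points)
        if not tp:
            # six representative time points spread over the treatment period
            tp = tuple(np.linspace(self.horizon_days / 6.0, self.horizon_days, 6))
        if max(tp) > self.horizon_days:
            raise ConfigError("time points must lie within the simulation horizon")
        object.__setattr__(self, "time_points", tp)

    @property
    def names(self) -> tuple:
        return tuple(self.nominal)

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        nom = np.array([self.nominal[n] for n in self.names])
        return self.bounds_factor[0] * nom, self.bounds_factor[1] * nom


@dataclass
class SobolDesign:
    """Paired sample matrices for total-effect estimation."""

    A: np.ndarray            # (N, d)
    B: np.ndarray            # (N, d)
    names: tuple

    @property
    def n_base(self) -> int:
        return self.A.shape[0]

    def ab_matrices(self):
        """Yield (j, AB_j): A with column j replaced by B's column j."""
        for j in range(self.A.shape[1]):
            ab = self.A.copy()
            ab[:, j] = self.B[:, j]
            yield j, ab


def sample_parameter_space(spec: GsaSpec) -> SobolDesign:
    """Low-discrepancy paired design over the [0.5, 2.0] x nominal box."""
    d = len(spec.names)
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # N need not be a power of two
        unit = sampler.random(spec.n)
    lo, hi = spec.box()
    A = lo + unit[:, :d] * (hi - lo)
    B = lo + unit[:, d:] * (hi - lo)
    return SobolDesign(A=A, B=B, names=spec.names)


@dataclass
class SobolIndices:
    """Total-effect indices per parameter and time point."""

    S_T: np.ndarray              # (d, n_times), NaN where variance vanished
    variance: np.ndarray         # (n_times,)
    names: tuple
    time_points: tuple
    degenerate: np.ndarray       # (n_times,) bool — zero output variance


def total_sobol_indices(model_fn, design: SobolDesign, time_points=None) -> SobolIndices:
    """Jansen's total-effect estimator on a paired design.

    ``model_fn`` maps a (S, d) parameter matrix to (S, n_times) outputs and
    must be finite on the design.  S_T_j = mean((f_A - f_AB_j)^2) / (2 Var),
    clipped to [0, 1 + 3 MC-standard-errors].  Time points with zero output
    variance are flagged and their indices set to NaN.
    """
    f_A = np.asarray(model_fn(design.A), dtype=float)
    f_B = np.asarray(model_fn(design.B), dtype=float)
    if f_A.ndim == 1:
        f_A, f_B = f_A[:, None], f_B[:, None]
    if not (np.isfinite(f_A).all() and np.isfinite(f_B).all()):
        raise DomainError("model output not finite on the sample design")
    variance = np.var(np.concatenate([f_A, f_B], axis=0), axis=0)
    degenerate = variance <= 1e-14 * np.maximum(np.mean(np.abs(f_A), axis=0) ** 2, 1e-300)

    N = design.n_base
    d = len(design.names)
    S_T = np.full((d, f_A.shape[1]), np.nan)
    for j, AB in design.ab_matrices():
        f_AB = np.asarray(model_fn(AB), dtype=float)
        if f_AB.ndim == 1:
            f_AB = f_AB[:, None]
        diff2 = (f_A - f_AB) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            est = np.mean(diff2, axis=0) / (2.0 * variance)
            mc_se = np.std(diff2, axis=0) / (np.sqrt(N) * 2.0 * variance)
        est = np.clip(est, 0.0, 1.0 + 3.0 * np.where(np.isfinite(mc_se), mc_se, 0.0))
        S_T[j] = np.where(degenerate, np.nan, est)
    if time_points is None:
        time_points = tuple(range(f_A.shape[1]))
    return SobolIndices(S_T=S_T, variance=variance, names=design.names,
                        time_points=tuple(time_points), degenerate=degenerate)


def freezing_error(indices: SobolIndices, p: float = 0.05) -> np.ndarray:
    """Cumulative parameter-freezing error bound per parameter.

    Per time point the bound is sqrt(S_T * Var(Y) / p): with probability at
    least 1 - p, fixing the parameter at a nominal value perturbs the output
    by less than this (Chebyshev-type bound on the variance attributed to
    the parameter, interactions included).  The per-time bounds are
    aggregated across the representative time points by root-sum-of-squares;
    degenerate (zero-variance) time points are excluded.
    """
    if not (0.0 < p < 1.0):
        raise ConfigError("probability level p must lie in (0, 1)")
    per_time = indices.S_T * indices.variance[None, :] / p
    per_time = np.where(np.isnan(per_time), 0.0, per_time)
    return np.sqrt(per_time.sum(axis=1))


def classify_sensitive(errors, names=None, threshold: float = 0.05):
    """Partition parameters into sensitive and redundant sets.

    A parameter is redundant iff its freezing error is below ``threshold``
    times the largest freezing error; the rule is invariant to common
    rescaling of all errors.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise DomainError("need at least one parameter")
    if names is None:
        names = tuple(range(errors.size))
    cutoff = threshold * errors.max()
    sensitive = tuple(n for n, e in zip(names, errors) if e >= cutoff)
    redundant = tuple(n for n, e in zip(names, errors) if e < cutoff)
    return sensitive, redundant


@dataclass
class SensitivityReport:
    """Tabular model-reduction report (parameter, error, % of max, class)."""

    table: pd.DataFrame
    spec: GsaSpec | None = None
    indices: SobolIndices | None = None

    @classmethod
    def from_errors(cls, names, errors, threshold: float = 0.05,
                    spec: GsaSpec | None = None, indices=None) -> "SensitivityReport":
        """Build the report from absolute freezing errors (any common scale)."""
        errors = np.asarray(errors, dtype=float)
        sensitive, _ = classify_sensitive(errors, names=names, threshold=threshold)
        max_err = errors.max()
        pct = 100.0 * errors / max_err if max_err > 0 else np.zeros_like(errors)
        table = pd.DataFrame({
            "parameter": list(names),
            "error": errors,
            "pct_of_max": pct,
            "classification": ["sensitive" if n in set(sensitive) else "redundant" for n in names],
        })
        return cls(table=table, spec=spec, indices=indices)

    @property
    def sensitive(self) -> tuple:
        return tuple(self.table.loc[self.table["classification"] == "sensitive", "parameter"])

    @property
    def redundant(self) -> tuple:
        return tuple(self.table.loc[self.table["classification"] == "redundant", "parameter"])

    def to_json_dict(self) -> dict:
        recs = self.table.to_dict(orient="records")
        meta = {}
        if self.spec is not None:
            meta = {"output": self.spec.output, "n": self.spec.n, "seed": self.spec.seed,
                    "p": self.spec.p, "threshold": self.spec.threshold,
                    "time_points": list(self.spec.time_points)}
        if self.indices is not None:
            meta["variance_per_time"] = list(map(float, self.indices.variance))
        return {"parameters": recs, "metadata": meta}


def _model_output_fn(spec: GsaSpec, patient: Patient):
    """Batched evaluator of the requested model output over the sample design."""
    from .estimate import ObservationSet, SimConfig, _BatchCost

    var = {"x_t": "x_t", "L": "L", "M": "dmcv"}[spec.output]
    records = [(t, var, 0.0, 1.0) for t in spec.time_points]
    obs = ObservationSet.from_records(records)
    cfg = SimConfig(regimen=spec.regimen, base=patient, horizon_days=spec.horizon_days)
    evaluator = _BatchCost(obs, cfg, free=spec.names)

    if spec.output == "M":
        m_in_idx = spec.names.index("M_in") if "M_in" in spec.names else None

        def fn(theta):
            pred = evaluator.predict(theta)["dmcv"]
            m_in = theta[:, m_in_idx] if m_in_idx is not None else patient.erythro.M_in
            return pred + np.atleast_1d(m_in)[:, None]
        return fn

    def fn(theta):
        return evaluator.predict(theta)[var]
    return fn


def run_gsa(spec: GsaSpec, patient: Patient | None = None) -> SensitivityReport:
    """End-to-end model reduction for one output: sample, estimate, classify."""
    patient = patient or Patient()
    design = sample_parameter_space(spec)
    fn = _model_output_fn(spec, patient)
    indices = total_sobol_indices(fn, design, time_points=spec.time_points)
    errors = freezing_error(indices, p=spec.p)
    return SensitivityReport.from_errors(spec.names, errors, threshold=spec.threshold,
                                         spec=spec, indices=indices)
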