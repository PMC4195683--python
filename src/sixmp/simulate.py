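"""Treatment-course simulation of the coupled PK -> PD cascade.

Scheduled oral doses are instantaneous boluses added to the gut compartment;
the RBC 6-TGN concentration produced by the metabolism model drives both
hematopoiesis models (one-directional coupling).  Two engines are available:

* ``"lsoda"`` (default) — scipy adaptive stiff-capable integration restarted
  at every dose event, rtol 1e-8 and state-scaled atol;
* ``"fast"`` — the vectorized fixed-step engine of :mod:`sixmp._fast`
  (closed-form plasma kinetics + RK4 hematopoiesis), accurate to ~1e-3 and
  used inside fitting / sensitivity / control loops.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import _fast
from .errors import ConfigError, DomainError, NumericalError
from .models import ErythroState, LeukoState, SixMPState, baseline_state
from .params import (
    ErythroParams,
    KG_PER_L_BLOOD,
    LeukoParams,
    Patient,
    SixMPParams,
    dose_mg_to_pmol,
)

#: Output variables of a treatment-course simulation and their units.
OUTPUT_UNITS = {
    "x_t": "pmol/8e8 RBC",
    "x_m": "pmol/8e8 RBC",
    "L": "cells/L",
    "M": "fL",
    "dmcv": "fL",
}

_REGIMEN_RE = re.compile(r"^daily:(?P<dose>[0-9.]+)mg(?::(?P<days>[0-9.]+)d)?$")


@dataclass(frozen=True)
class DoseRegimen:
    """Timed oral 6-MP doses.

    ``events`` is a sequence of (time_days, dose_mg) with strictly increasing
    non-negative times and non-negative doses.
    """

    events: tuple = ()
    description: str = ""

    def __post_init__(self):
        times = [t for t, _ in self.events]
        doses = [d for _, d in self.events]
        if any(t < 0 for t in times):
            raise DomainError("dose times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError("dose times must be strictly increasing")
        if any(d < 0 for d in doses):
            raise DomainError("doses must be non-negative")
        object.__setattr__(self, "events", tuple((float(t), float(d)) for t, d in self.events))

    @classmethod
    def daily(cls, dose_mg: float, days: int, start: float = 0.0) -> "DoseRegimen":
        """One ``dose_mg`` bolus per day for ``days`` days, starting at ``start``."""
        events = tuple((start + i, float(dose_mg)) for i in range(int(days)))
        return cls(events=events, description=f"daily:{dose_mg:g}mg:{int(days)}d")

    @classmethod
    def parse(cls, text: str, default_days: int = 112) -> "DoseRegimen":
        """Parse a regimen spec such as ``daily:75mg:75d``."""
        m = _REGIMEN_RE.match(text.strip())
        if not m:
            raise ConfigError(f"unrecognized regimen spec {text!r} (expected e.g. 'daily:75mg:75d')")
        days = int(float(m.group("days"))) if m.group("days") else default_days
        return cls.daily(float(m.group("dose")), days)

    def scaled(self, factor: float) -> "DoseRegimen":
        return DoseRegimen(
            events=tuple((t, d * factor) for t, d in self.events),
            description=f"{self.description}*{factor:g}" if self.description else "",
        )

    @property
    def max_time(self) -> float:
        return self.events[-1][0] if self.events else 0.0

    def arrays_pmol(self) -> tuple[np.ndarray, np.ndarray]:
        times = np.array([t for t, _ in self.events], dtype=float)
        pmol = np.array([dose_mg_to_pmol(d) for _, d in self.events], dtype=float)
        return times, pmol

    @property
    def total_mg(self) -> float:
        return sum(d for _, d in self.events)


@dataclass
class Trajectory:
    """Sampled treatment-course outputs on a common time grid."""

    times: np.ndarray
    values: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise DomainError("trajectory times must be sorted")
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}

    def at(self, variable: str, times) -> np.ndarray:
        """Linear interpolation of one output at arbitrary times."""
        return np.interp(np.asarray(times, dtype=float), self.times, self.values[variable])

    def to_frame(self):
        """Tidy frame with columns time_days, variable, value, unit."""
        import pandas as pd

        rows = {
            "time_days": np.concatenate([self.times] * len(self.values)) if self.values else np.array([]),
            "variable": np.concatenate([[k] * self.times.size for k in self.values]) if self.values else np.array([]),
            "value": np.concatenate(list(self.values.values())) if self.values else np.array([]),
        }
        frame = pd.DataFrame(rows)
        frame["unit"] = frame["variable"].map(lambda v: OUTPUT_UNITS.get(v, ""))
        return frame


def marrow_to_blood(count_per_kg):
    """Convert marrow cells/kg to circulating cells/L (15.5 kg per liter of blood)."""
    arr = np.asarray(count_per_kg, dtype=float)
    if np.any(arr < 0):
        raise DomainError("cell count must be non-negative")
    out = KG_PER_L_BLOOD * arr
    return out if out.shape else float(out)


def delta_mcv(traj: Trajectory, baseline: float) -> np.ndarray:
    """Pointwise MCV change from the untreated baseline."""
    if baseline <= 0:
        raise DomainError("baseline MCV must be positive")
    return traj.values["M"] - baseline


def _params_hash(*param_sets) -> str:
    payload = json.dumps([p.to_dict() for p in param_sets], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def simulate_course(
    regimen: DoseRegimen,
    pk: SixMPParams | None = None,
    leuko: LeukoParams | None = None,
    erythro: ErythroParams | None = None,
    horizon_days: float = 112.0,
    output_times=None,
    engine: str = "lsoda",
    start_time: float = 0.0,
    initial_state: tuple | None = None,
    rtol: float = 1e-8,
) -> Trajectory:
    """Simulate the full treatment course and sample the observable outputs.

    The system starts at the drug-free baseline unless ``initial_state`` (a
    (SixMPState, LeukoState, ErythroState) triple at ``start_time``) is given.
    ``output_times`` defaults to a 1-day grid.  Deterministic for fixed inputs.
    """
    pk = pk or SixMPParams()
    leuko = leuko or LeukoParams()
    erythro = erythro or ErythroParams()
    if regimen.events and regimen.max_time > horizon_days:
        raise DomainError("horizon must cover the last dose event")
    if output_times is None:
        output_times = np.arange(start_time, horizon_days + 1e-9, 1.0)
    output_times = np.asarray(output_times, dtype=float)

    if initial_state is None:
        leuko0 = baseline_state(leuko)
        ery0 = baseline_state(erythro)
        initial_state = (SixMPState(), leuko0, ery0)
    pk0, leuko0, ery0 = initial_state
    m_baseline = erythro.M_in

    if engine == "fast":
        sampled = _run_fast(regimen, pk, leuko, erythro, horizon_days, output_times,
                            start_time, pk0, leuko0, ery0)
    elif engine == "lsoda":
        sampled = _run_lsoda(regimen, pk, leuko, erythro, horizon_days, output_times,
                             start_time, pk0, leuko0, ery0, rtol)
    else:
        raise ConfigError(f"unknown engine {engine!r}")

    final_state = sampled.pop("_final_state")
    sampled["dmcv"] = sampled["M"] - m_baseline
    return Trajectory(
        times=output_times,
        values=sampled,
        metadata={
            "params_hash": _params_hash(pk, leuko, erythro),
            "regimen": regimen.description,
            "engine": engine,
            "m_baseline": m_baseline,
            "final_state": final_state,
        },
    )


def simulate_patient(patient: Patient, regimen: DoseRegimen, **kwargs) -> Trajectory:
    """Convenience wrapper over :func:`simulate_course` for a Patient bundle."""
    return simulate_course(regimen, pk=patient.pk, leuko=patient.leuko,
                           erythro=patient.erythro, **kwargs)


# ---------------------------------------------------------------------------
# engines

def _run_fast(regimen, pk, leuko, erythro, horizon, output_times, start_time,
              pk0, leuko0, ery0, dt_pk=_fast.DEFAULT_DT_PK, dt_pd=_fast.DEFAULT_DT_PD):
    span = horizon - start_time
    grid = _fast.uniform_grid(span, dt_pk, start=start_time)
    ev_t, ev_pmol = regimen.arrays_pmol()
    pkc = _fast.pk_curves(pk.to_dict(), ev_t, ev_pmol, grid, x0=pk0.as_array()[None, :])

    n_pd = max(1, int(round(span / dt_pd)))
    dt_pd = span / n_pd
    half_times = start_time + np.arange(2 * n_pd + 1) * (dt_pd / 2.0)
    xt_half = _fast.resample_uniform(pkc["x_t"], grid[0], grid[1] - grid[0], half_times)
    pd_times = half_times[::2]

    leuko_traj = _fast.pd_curves("leuko", leuko.to_dict(), xt_half, dt_pd,
                                 leuko0.as_array()[None, :])
    ery_traj = _fast.pd_curves("erythro", erythro.to_dict(), xt_half, dt_pd,
                               ery0.as_array()[None, :])

    def _interp(times_src, vals, t):
        return np.interp(t, times_src, vals)

    final_state = (
        SixMPState(x_g=pkc["x_g"][0, -1], x_p=pkc["x_p"][0, -1],
                   x_t=pkc["x_t"][0, -1], x_m=pkc["x_m"][0, -1]),
        LeukoState.from_array(leuko_traj[0, -1]),
        ErythroState.from_array(ery_traj[0, -1]),
    )
    return {
        "x_t": _interp(grid, pkc["x_t"][0], output_times),
        "x_m": _interp(grid, pkc["x_m"][0], output_times),
        "L": _interp(pd_times, leuko_traj[0, :, 4], output_times),
        "M": _interp(pd_times, ery_traj[0, :, 5], output_times),
        "_final_state": final_state,
    }


def _run_lsoda(regimen, pk, leuko, erythro, horizon, output_times, start_time,
               pk0, leuko0, ery0, rtol):
    from .models import erythro_rhs, leuko_rhs, sixmp_rhs

    y0 = np.concatenate([pk0.as_array(), leuko0.as_array(), ery0.as_array()])
    scale = np.maximum(np.abs(y0), [1e6, 1e6, 1.0, 1.0, 1e8, 1e8, 1e8, 1e8, 1e8, 1e8,
                                    1e8, 1e8, 1e8, 1e8, 1.0])
    atol = 1e-10 * scale

    def rhs(t, y):
        pk_d = sixmp_rhs(SixMPState.from_array(np.maximum(y[:4], 0.0)), pk)
        x_t = max(y[2], 0.0)
        leu_d = leuko_rhs(LeukoState.from_array(np.maximum(y[4:9], 0.0)), leuko, x_t)
        ery_arr = y[9:15].copy()
        ery_arr[:5] = np.maximum(ery_arr[:5], 0.0)
        ery_d = erythro_rhs(ErythroState.from_array(ery_arr), erythro, x_t)
        return np.concatenate([pk_d.as_array(), leu_d.as_array(), ery_d.as_array()])

    ev_t, ev_pmol = regimen.arrays_pmol()
    keep = (ev_t >= start_time - 1e-12) & (ev_t <= horizon + 1e-12)
    ev_t, ev_pmol = ev_t[keep], ev_pmol[keep]
    bounds = np.concatenate(([start_time], ev_t, [horizon]))
    out = {k: np.empty_like(output_times) for k in ("x_t", "x_m", "L", "M")}
    filled = np.zeros(output_times.shape, dtype=bool)
    y = y0.copy()
    for i in range(len(bounds) - 1):
        if i > 0:
            y[0] += ev_pmol[i - 1]
        t0, t1 = bounds[i], bounds[i + 1]
        if t1 - t0 <= 1e-12:
            continue
        last = i + 1 == len(bounds) - 1
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol,
                        dense_output=True)
        if not sol.success:
            raise NumericalError(f"LSODA failed on segment [{t0:g}, {t1:g}] days: {sol.message}")
        mask = (~filled) & (output_times >= t0 - 1e-9) & (
            (output_times <= t1 + 1e-9) if last else (output_times < t1 - 1e-9))
        if mask.any():
            states = sol.sol(np.clip(output_times[mask], t0, t1))
            out["x_t"][mask] = states[2]
            out["x_m"][mask] = states[3]
            out["L"][mask] = states[8]
            out["M"][mask] = states[14]
            filled |= mask
        y = sol.y[:, -1]
    if not filled.all():
        for key, row in (("x_t", 2), ("x_m", 3), ("L", 8), ("M", 14)):
            out[key][~filled] = y[row]
    out["_final_state"] = (SixMPState.from_array(y[:4]), LeukoState.from_array(y[4:9]),
                           ErythroState.from_array(y[9:15]))
    return out
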