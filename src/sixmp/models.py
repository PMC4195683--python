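"""Right-hand sides and steady states of the three coupled ODE systems.

The cascade is one-directional: oral dosing drives the 6-MP metabolism
system, whose RBC 6-TGN concentration ``x_t`` is the sole coupling variable
into both hematopoiesis systems.

6-MP metabolism (gut -> plasma -> intracellular metabolites)::

    dx_g/dt = u(t) - k_a*x_g
    dx_p/dt = k_a*x_g - k_e*x_p
    dx_t/dt = f_tgn * k_pt * x_p/(K_t + x_p) - k_te*x_t
    dx_m/dt = f_memp * k_pm * x_p/(K_m + x_p) - k_me*x_m

where (f_memp, f_tgn) = (e/e_max, 1 - e/e_max) is the TPMT activity
partition.  The conversion fluxes do not deplete plasma 6-MP: ``x_p`` is an
amount (pmol) while the metabolites are RBC concentrations (pmol/8e8 RBC);
the formation-rate constants absorb the volume/partition factors and
first-pass elimination dominates the plasma balance (half-life 1.2 h).

Hematopoiesis (per lineage, three identical transit compartments)::

    dS/dt  = [fb(C_circ) - E(x_t) - k_t - k_s] * S
    dC1/dt = k_t*(S - C1);  dC2/dt = k_t*(C1 - C2);  dC3/dt = k_t*(C2 - C3)

with circulating leukocytes ``dL/dt = kappa*k_tl*C_L3 - k_dl*L`` (cells/L)
and circulating RBCs ``dR/dt = k_tr*C_R3 - k_dr*R`` (cells/kg).  MCV::

    dM/dt = (k_tr*C_R3/R)*(M_in - M) + k_m6*x_t

``fb`` is a decreasing Hill feedback and ``E`` an increasing Hill kill term;
only the proliferating compartment S is drug-sensitive.  ``k_s`` is the
background progenitor attrition that separates the steady-state proliferation
demand (0.157 d^-1 for leukopoiesis) from the transit rate (0.1207 d^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InfeasibleBaselineError, InvalidActivityError, SingularStateError
from .params import ErythroParams, LeukoParams, SixMPParams


# ---------------------------------------------------------------------------
# state containers

@dataclass(frozen=True)
class SixMPState:
    """Amounts/concentrations of 6-MP and its metabolites."""

    x_g: float = 0.0   # 6-MP in gut, pmol
    x_p: float = 0.0   # 6-MP in plasma, pmol
    x_t: float = 0.0   # 6-TGN in RBCs, pmol/8e8 RBC
    x_m: float = 0.0   # MeMP in RBCs, pmol/8e8 RBC

    def as_array(self) -> np.ndarray:
        return np.array([self.x_g, self.x_p, self.x_t, self.x_m], dtype=float)

    @classmethod
    def from_array(cls, a) -> "SixMPState":
        return cls(*map(float, a))


@dataclass(frozen=True)
class LeukoState:
    """Marrow leukocyte lineage (cells/kg) and circulating count (cells/L)."""

    S_L: float
    C_L1: float
    C_L2: float
    C_L3: float
    L: float

    def as_array(self) -> np.ndarray:
        return np.array([self.S_L, self.C_L1, self.C_L2, self.C_L3, self.L], dtype=float)

    @classmethod
    def from_array(cls, a) -> "LeukoState":
        return cls(*map(float, a))


@dataclass(frozen=True)
class ErythroState:
    """Marrow erythroid lineage, circulating RBCs (cells/kg) and MCV (fL)."""

    S_R: float
    C_R1: float
    C_R2: float
    C_R3: float
    R: float
    M: float

    def as_array(self) -> np.ndarray:
        return np.array([self.S_R, self.C_R1, self.C_R2, self.C_R3, self.R, self.M], dtype=float)

    @classmethod
    def from_array(cls, a) -> "ErythroState":
        return cls(*map(float, a))


# ---------------------------------------------------------------------------
# elementary rate laws

def tpmt_partition(e: float, e_max: float) -> tuple[float, float]:
    """Split converted 6-MP between the two pathways by TPMT activity.

    Returns ``(f_memp, f_tgn) = (e/e_max, 1 - e/e_max)``: the methylation
    share grows with the patient's TPMT activity, the 6-TGN share is the
    complement, and the two always sum to one.
    """
    if e_max <= 0:
        raise InvalidActivityError(f"e_max must be positive, got {e_max}")
    if not (0.0 <= e <= e_max):
        raise InvalidActivityError(f"TPMT activity e={e} outside [0, {e_max}]")
    f_memp = e / e_max
    return f_memp, 1.0 - f_memp


def feedback_rate(C, k_max: float, theta: float, s: float):
    """Decreasing Hill feedback: k_max * theta^s / (theta^s + C^s).

    Receptor-theoretic saturating form shared by both lineages; equals
    ``k_max`` as the circulating count C -> 0 and ``k_max/2`` at C = theta.
    """
    if k_max <= 0 or theta <= 0 or s <= 0:
        raise DomainError("feedback_rate requires k_max, theta, s > 0")
    ratio = np.power(np.asarray(C, dtype=float) / theta, s)
    out = k_max / (1.0 + ratio)
    return out if out.shape else float(out)


def hill_effect(x_t, E_max: float, EC50: float, h: float):
    """Drug-induced kill rate: E_max * x_t^h / (EC50^h + x_t^h)."""
    if E_max <= 0 or EC50 <= 0 or h <= 0:
        raise DomainError("hill_effect requires E_max, EC50, h > 0")
    x = np.asarray(x_t, dtype=float)
    if np.any(x < 0):
        raise DomainError("6-TGN level must be non-negative")
    ratio = np.power(x / EC50, h)
    out = E_max * ratio / (1.0 + ratio)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# right-hand sides

def _check_nonneg(arr, what: str) -> None:
    if np.any(np.asarray(arr) < 0):
        raise DomainError(f"negative {what} state")


def sixmp_rhs(state: SixMPState, params: SixMPParams, dose_rate: float = 0.0) -> SixMPState:
    """Time derivative of the 6-MP metabolism state.

    ``dose_rate`` is a continuous gut input in pmol/day; scheduled oral
    doses are instead applied as instantaneous additions to ``x_g`` by the
    simulator.
    """
    a = state.as_array()
    _check_nonneg(a, "6-MP")
    f_memp, f_tgn = tpmt_partition(params.e, params.e_max)
    x_g, x_p, x_t, x_m = a
    return SixMPState(
        x_g=dose_rate - params.k_a * x_g,
        x_p=params.k_a * x_g - params.k_e * x_p,
        x_t=f_tgn * params.k_pt * x_p / (params.K_t + x_p) - params.k_te * x_t,
        x_m=f_memp * params.k_pm * x_p / (params.K_m + x_p) - params.k_me * x_m,
    )


def leuko_rhs(state: LeukoState, params: LeukoParams, x_t: float = 0.0) -> LeukoState:
    """Time derivative of the leukopoiesis state at 6-TGN level ``x_t``."""
    a = state.as_array()
    _check_nonneg(a, "leukopoiesis")
    S, C1, C2, C3, L = a
    net = (
        feedback_rate(L, params.k_pl, params.theta_L, params.s_l)
        - hill_effect(x_t, params.EL_max, params.ECL_50, params.h_l)
        - params.k_tl
        - params.k_sl
    )
    return LeukoState(
        S_L=net * S,
        C_L1=params.k_tl * (S - C1),
        C_L2=params.k_tl * (C1 - C2),
        C_L3=params.k_tl * (C2 - C3),
        L=params.kappa * params.k_tl * C3 - params.k_dl * L,
    )


def erythro_rhs(state: ErythroState, params: ErythroParams, x_t: float = 0.0) -> ErythroState:
    """Time derivative of the erythropoiesis/MCV state at 6-TGN level ``x_t``."""
    a = state.as_array()
    _check_nonneg(a[:5], "erythropoiesis")
    S, C1, C2, C3, R, M = a
    if R <= 0:
        raise SingularStateError("circulating RBC count must be positive for MCV dynamics")
    net = (
        feedback_rate(R, params.k_pr, params.theta_R, params.s_r)
        - hill_effect(x_t, params.ER_max, params.ECR_50, params.h_r)
        - params.k_tr
        - params.k_sr
    )
    return ErythroState(
        S_R=net * S,
        C_R1=params.k_tr * (S - C1),
        C_R2=params.k_tr * (C1 - C2),
        C_R3=params.k_tr * (C2 - C3),
        R=params.k_tr * C3 - params.k_dr * R,
        M=(params.k_tr * C3 / R) * (params.M_in - M) + params.k_m6 * x_t,
    )


# ---------------------------------------------------------------------------
# drug-free steady states

def equilibrium_circulating(params: LeukoParams | ErythroParams) -> float:
    """Drug-free equilibrium circulating count implied by the feedback law.

    Solves fb(C) = k_t + k_s by inverting the Hill feedback:
    C* = theta * ((k_max - k)/k)^(1/s).
    """
    if isinstance(params, LeukoParams):
        k_max, theta, s = params.k_pl, params.theta_L, params.s_l
    else:
        k_max, theta, s = params.k_pr, params.theta_R, params.s_r
    demand = params.baseline_proliferation
    if k_max <= demand:
        raise InfeasibleBaselineError(
            f"no positive equilibrium: maximal proliferation {k_max} <= transit+attrition {demand}"
        )
    return theta * ((k_max - demand) / demand) ** (1.0 / s)


def baseline_state(
    params: LeukoParams | ErythroParams,
    target_circulating: float | None = None,
    rtol: float = 1e-6,
):
    """Drug-free steady state of a hematopoiesis model.

    All transit compartments equal the proliferating pool at equilibrium
    (equal rates through the chain); the pool size follows from the
    circulating-count balance.  If ``target_circulating`` is given it is
    checked against the equilibrium implied by the parameters (relative
    tolerance ``rtol``) — defaults are calibrated so the two coincide.
    """
    c_eq = equilibrium_circulating(params)
    if target_circulating is not None:
        if abs(target_circulating - c_eq) > rtol * abs(c_eq):
            raise InfeasibleBaselineError(
                f"target circulating count {target_circulating:g} inconsistent with "
                f"parameter-implied equilibrium {c_eq:g}"
            )
        c_eq = float(target_circulating)
    if isinstance(params, LeukoParams):
        chain = params.k_dl * c_eq / (params.kappa * params.k_tl)
        return LeukoState(S_L=chain, C_L1=chain, C_L2=chain, C_L3=chain, L=c_eq)
    chain = params.k_dr * c_eq / params.k_tr
    return ErythroState(S_R=chain, C_R1=chain, C_R2=chain, C_R3=chain, R=c_eq, M=params.M_in)
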