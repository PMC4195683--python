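"""Kinetic parameter sets for the 6-MP metabolism and hematopoiesis models.

Three coupled semi-mechanistic systems are parameterized here:

* :class:`SixMPParams` — oral 6-MP absorption/elimination and its two
  competing intracellular conversion pathways (HGPRT -> 6-TGN, the active
  cytotoxic metabolites; TPMT -> MeMP, the lumped methylated metabolites).
* :class:`LeukoParams` — transit-compartment leukopoiesis with circulating-
  count feedback on progenitor proliferation and a Hill-type 6-TGN kill term.
* :class:`ErythroParams` — the mirrored erythropoiesis system plus mean
  corpuscular volume (MCV) dynamics, the surrogate efficacy marker.

Default values are the package's "average patient".  They are produced by the
deterministic calibration in :mod:`sixmp.calibrate`, which anchors them to
reported clinical quantities (1.2 h plasma half-life, transit rate
0.1207 d^-1, steady-state proliferation 0.157 d^-1, ECL_50 = 84,
120-day RBC lifespan, ~8 fL MCV-shift plateau at a sustained 6-TGN level of
158 pmol/8e8 RBC, median/maximum TPMT activity 13/26, baseline leukocyte
count 6e9 cells/L).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, fields

from .errors import DomainError, InvalidActivityError

#: Molar mass of 6-mercaptopurine, g/mol (anhydrous).
MOLAR_MASS_6MP = 152.177

#: pmol of 6-MP per mg of oral dose.
PMOL_PER_MG = 1e9 / MOLAR_MASS_6MP

#: Marrow-to-blood conversion: kg of body mass per liter of blood.
KG_PER_L_BLOOD = 15.5

#: Standard adult-equivalent daily oral 6-MP dose, mg/day.
STANDARD_DOSE_MG = 75.0

#: Clinically proposed therapeutic window for RBC 6-TGN, pmol/8e8 RBC.
THERAPEUTIC_WINDOW_TGN = (235.0, 400.0)


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not (value > 0) or not math.isfinite(value):
            raise DomainError(f"{type(obj).__name__}.{name} must be positive and finite, got {value!r}")


class _ParamBase:
    """Shared plumbing: dict round-trip and field replacement."""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict):
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DomainError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
        base = {f.name: getattr(cls(), f.name) for f in fields(cls)}
        base.update(data)
        return cls(**base)

    def replace(self, **overrides):
        return dataclasses.replace(self, **overrides)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class SixMPParams(_ParamBase):
    """6-MP metabolism parameters.

    Rates are per day; metabolite formation capacities are in
    pmol/8e8 RBC/day; Michaelis constants are in pmol of plasma 6-MP.
    ``e`` is the patient's TPMT activity on the same scale as ``e_max``;
    a fraction e/e_max of the converted drug follows the methylation
    pathway and the remainder forms 6-TGN.
    """

    k_a: float = 4.8            # gut absorption rate, 1/day
    k_e: float = 13.862943611198906   # plasma elimination, ln2/(1.2 h)
    k_pt: float = 25.1          # max 6-TGN formation rate, pmol/8e8 RBC/day
    K_t: float = 1.0e4          # Michaelis constant, 6-TGN pathway, pmol
    k_pm: float = 600.0         # max MeMP formation rate, pmol/8e8 RBC/day
    K_m: float = 1.0e4          # Michaelis constant, MeMP pathway, pmol
    k_te: float = 0.0661        # 6-TGN elimination, 1/day
    k_me: float = 0.1           # MeMP elimination, 1/day
    e: float = 13.0             # patient TPMT activity
    e_max: float = 26.0         # maximum TPMT activity

    def __post_init__(self):
        _require_positive(self, ("k_a", "k_e", "k_pt", "K_t", "k_pm", "K_m", "k_te", "k_me", "e_max"))
        if not (0.0 <= self.e <= self.e_max):
            raise InvalidActivityError(f"TPMT activity e={self.e} outside [0, e_max={self.e_max}]")


@dataclass(frozen=True)
class LeukoParams(_ParamBase):
    """Leukopoiesis parameters (Friberg-style transit chain).

    The proliferating progenitor pool S_L self-renews at a rate modulated by
    a decreasing Hill feedback of the circulating count (G-CSF surrogate),
    loses cells to maturation (k_tl, three identical transit compartments),
    to background attrition (k_sl), and to the 6-TGN-driven Hill kill term.
    ``kappa`` converts marrow cells/kg into circulating cells/L of blood.
    """

    k_pl: float = 0.314         # maximal proliferation rate, 1/day
    theta_L: float = 6.0e9      # feedback half-effect leukocyte level, cells/L
    s_l: float = 1.0            # feedback steepness
    k_tl: float = 0.1207        # transit/maturation rate, 1/day
    k_sl: float = 0.0363        # progenitor attrition rate, 1/day
    k_dl: float = 2.4           # circulating leukocyte death rate, 1/day
    EL_max: float = 0.075508    # maximal drug kill rate, 1/day (calibrated)
    ECL_50: float = 84.0        # 6-TGN level at half-maximal kill
    h_l: float = 1.0            # drug-effect Hill coefficient
    kappa: float = KG_PER_L_BLOOD  # marrow-to-blood conversion, kg/L

    def __post_init__(self):
        _require_positive(self, self.field_names())

    @property
    def baseline_proliferation(self) -> float:
        """Net proliferation demand at equilibrium: k_tl + k_sl."""
        return self.k_tl + self.k_sl


@dataclass(frozen=True)
class ErythroParams(_ParamBase):
    """Erythropoiesis and MCV-dynamics parameters.

    Mirrors the leukopoiesis structure (EPO-mediated feedback, 3 transit
    compartments) with circulating RBCs kept in cells/kg.  MCV of the
    circulating pool relaxes toward the release volume M_in through cell
    turnover and is pushed up linearly by 6-TGN exposure (k_m6).
    """

    k_pr: float = 0.56          # maximal proliferation rate, 1/day
    theta_R: float = 3.5e11     # feedback half-effect RBC level, cells/kg
    s_r: float = 0.2            # feedback steepness (<< s_l: weaker feedback)
    k_tr: float = 0.25          # transit rate, 1/day
    k_sr: float = 0.03          # progenitor attrition rate, 1/day
    k_dr: float = 1.0 / 120.0   # RBC death rate (120-day lifespan), 1/day
    ER_max: float = 0.01        # maximal drug kill rate, 1/day
    ECR_50: float = 150.0       # half-effect 6-TGN level
    h_r: float = 1.0            # Hill coefficient
    M_in: float = 85.0          # MCV of newly released RBCs, fL
    k_m6: float = 4.219409282700422e-04  # fL per (pmol/8e8 RBC) per day

    def __post_init__(self):
        _require_positive(self, self.field_names())

    @property
    def baseline_proliferation(self) -> float:
        return self.k_tr + self.k_sr


@dataclass(frozen=True)
class Patient:
    """A virtual or fitted patient: one parameter set per model."""

    pk: SixMPParams = SixMPParams()
    leuko: LeukoParams = LeukoParams()
    erythro: ErythroParams = ErythroParams()
    id: str = "average"

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "pk": self.pk.to_dict(),
            "leuko": self.leuko.to_dict(),
            "erythro": self.erythro.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Patient":
        return cls(
            pk=SixMPParams.from_dict(data.get("pk", {})),
            leuko=LeukoParams.from_dict(data.get("leuko", {})),
            erythro=ErythroParams.from_dict(data.get("erythro", {})),
            id=data.get("id", "patient"),
        )

    def with_overrides(self, overrides: dict, id: str | None = None) -> "Patient":
        """Return a copy with named parameters replaced.

        ``overrides`` maps bare parameter names (e.g. ``"k_pt"``) to values;
        each name must belong to exactly one of the three parameter sets.
        """
        pk_over, leuko_over, ery_over = {}, {}, {}
        for name, value in overrides.items():
            target = _locate_param(name)
            {"pk": pk_over, "leuko": leuko_over, "erythro": ery_over}[target][name] = value
        return Patient(
            pk=self.pk.replace(**pk_over) if pk_over else self.pk,
            leuko=self.leuko.replace(**leuko_over) if leuko_over else self.leuko,
            erythro=self.erythro.replace(**ery_over) if ery_over else self.erythro,
            id=id if id is not None else self.id,
        )

    def get_param(self, name: str) -> float:
        return getattr(getattr(self, _locate_param(name)), name)


_PARAM_LOCATION: dict[str, str] = {}
for _cls, _label in ((SixMPParams, "pk"), (LeukoParams, "leuko"), (ErythroParams, "erythro")):
    for _f in fields(_cls):
        if _f.name in _PARAM_LOCATION:  # pragma: no cover - defensive
            raise RuntimeError(f"ambiguous parameter name {_f.name}")
        _PARAM_LOCATION[_f.name] = _label


def _locate_param(name: str) -> str:
    try:
        return _PARAM_LOCATION[name]
    except KeyError:
        raise DomainError(f"unknown model parameter {name!r}") from None


def dose_mg_to_pmol(dose_mg: float) -> float:
    """Convert an oral 6-MP dose in mg to pmol (molar mass 152.177 g/mol)."""
    if dose_mg < 0:
        raise DomainError(f"dose must be non-negative, got {dose_mg}")
    return dose_mg * PMOL_PER_MG
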