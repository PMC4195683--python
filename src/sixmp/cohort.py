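"""Patient fixtures, virtual cohorts and synthetic observation generation.

The seven reported patient-specific 6-MP parameter pairs are shipped verbatim
as fixtures.  The accompanying leukopoiesis (8) and MCV (10) patient sets
are *synthetic stand-ins* — lognormal spread around the average patient with
a fixed seed — sized to reproduce the 7x8 = 56 and 7x10 = 70 virtual-patient
cross-combinations.  Observation noise emulates the reported inter-assay
variability: multiplicative lognormal with 18% CV for 6-TGN and 22% for
MeMP, plus typical CBC analytics for the hematological outputs (10% CV
leukocytes, 1 fL additive MCV-shift noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError
from .estimate import ObservationSet
from .params import Patient
from .simulate import DoseRegimen, Trajectory, simulate_course

#: Reported patient-specific 6-MP parameters: (k_pt, k_te) per patient.
TABLE5_6MP = (
    (38.4, 0.0646),
    (41.4, 0.0815),
    (23.9, 0.0604),
    (18.76, 0.0453),
    (17.4, 0.0788),
    (15.83, 0.0867),
    (20.04, 0.0452),
)

#: Default assay/analytic coefficients of variation per observed variable.
DEFAULT_CV = {"x_t": 0.18, "x_m": 0.22, "L": 0.10}

#: Additive noise SD (same unit as the variable) where CV is inappropriate.
DEFAULT_ADDITIVE_SD = {"dmcv": 1.0}

_SYNTHETIC_PD_SEED = 20141013   # fixed: fixtures are part of the study conditions
_SYNTHETIC_PD_CV = 0.30

#: Parameters spread across synthetic PD patients.  Chosen among the
#: drug-response/turnover parameters so every synthetic patient shares the
#: same drug-free baseline (the feedback balance is untouched).
_LEUKO_VARIED = ("EL_max", "ECL_50", "k_dl")
_ERYTHRO_VARIED = ("ER_max", "ECR_50", "k_m6")


@dataclass(frozen=True)
class PatientFixture:
    """Named parameter overrides defining one fixture patient."""

    id: str
    overrides: dict
    source: str = ""

    def to_patient(self, base: Patient | None = None) -> Patient:
        base = base or Patient()
        return base.with_overrides(dict(self.overrides), id=self.id)

    def to_dict(self) -> dict:
        return {"id": self.id, "overrides": dict(self.overrides), "source": self.source}

    @classmethod
    def from_dict(cls, data: dict) -> "PatientFixture":
        return cls(id=data["id"], overrides=dict(data["overrides"]), source=data.get("source", ""))


def load_table5() -> list[PatientFixture]:
    """The 7 reported patient-specific (k_pt, k_te) pairs, verbatim."""
    return [
        PatientFixture(id=f"6mp-{i + 1}", overrides={"k_pt": k_pt, "k_te": k_te},
                       source="reported patient-specific 6-MP parameters")
        for i, (k_pt, k_te) in enumerate(TABLE5_6MP)
    ]


def _synthetic_pd_fixtures(kind: str, n: int) -> list[PatientFixture]:
    base = Patient()
    varied = _LEUKO_VARIED if kind == "leuko" else _ERYTHRO_VARIED
    rng = np.random.default_rng(_SYNTHETIC_PD_SEED if kind == "leuko" else _SYNTHETIC_PD_SEED + 1)
    sigma = np.sqrt(np.log(1.0 + _SYNTHETIC_PD_CV**2))
    fixtures = []
    for i in range(n):
        overrides = {}
        for name in varied:
            nominal = base.get_param(name)
            overrides[name] = float(nominal * np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2))
        fixtures.append(PatientFixture(
            id=f"{kind}-{i + 1}", overrides=overrides,
            source=f"synthetic stand-in ({kind} response, lognormal CV {_SYNTHETIC_PD_CV:.0%})"))
    return fixtures


def load_leuko_fixtures(n: int = 8) -> list[PatientFixture]:
    """Synthetic leukopoiesis patient set (default 8, for the 56-patient cohort)."""
    return _synthetic_pd_fixtures("leuko", n)


def load_erythro_fixtures(n: int = 10) -> list[PatientFixture]:
    """Synthetic MCV patient set (default 10, for the 70-patient cohort)."""
    return _synthetic_pd_fixtures("erythro", n)


def make_virtual_cohort(pk_sets, pd_sets, base: Patient | None = None) -> list[Patient]:
    """Cartesian cross-combination of PK and PD fixtures into virtual patients."""
    if not pk_sets or not pd_sets:
        raise DomainError("both fixture lists must be non-empty")
    base = base or Patient()
    cohort = []
    for pk_fix in pk_sets:
        for pd_fix in pd_sets:
            patient = base.with_overrides({**pk_fix.overrides, **pd_fix.overrides},
                                          id=f"{pk_fix.id}+{pd_fix.id}")
            cohort.append(patient)
    return cohort


def generate_observations(
    patient: Patient,
    regimen: DoseRegimen,
    schedule: dict,
    cv_map: dict | None = None,
    seed: int = 0,
    additive_sd_map: dict | None = None,
    engine: str = "fast",
    replicates: int = 1,
) -> ObservationSet:
    """Simulate truth and add assay noise; seed-deterministic.

    ``schedule`` maps variable names to sampling times (days).  Multiplicative
    noise is lognormal parameterized for an unbiased mean at the given CV;
    variables in ``additive_sd_map`` get additive Gaussian noise instead.
    ``replicates`` repeats the noise draw (one simulation) so assay scatter
    can be characterized without re-integrating.
    """
    cv_map = DEFAULT_CV if cv_map is None else cv_map
    additive_sd_map = DEFAULT_ADDITIVE_SD if additive_sd_map is None else additive_sd_map
    for cv in cv_map.values():
        if cv < 0:
            raise DomainError("coefficients of variation must be non-negative")
    all_times = np.unique(np.concatenate([np.asarray(t, dtype=float) for t in schedule.values()]))
    horizon = max(float(all_times.max()), regimen.max_time + 1.0)
    traj = simulate_course(regimen, pk=patient.pk, leuko=patient.leuko, erythro=patient.erythro,
                           horizon_days=horizon, output_times=all_times, engine=engine)
    rng = np.random.default_rng(seed)
    records = []
    for var in sorted(schedule):
        times = np.asarray(schedule[var], dtype=float)
        truth = traj.at(var, times)[None, :]
        if var in additive_sd_map:
            noisy = truth + additive_sd_map[var] * rng.standard_normal((replicates, times.size))
        else:
            cv = cv_map.get(var, 0.0)
            if cv > 0:
                sigma = np.sqrt(np.log(1.0 + cv**2))
                z = rng.standard_normal((replicates, times.size))
                noisy = truth * np.exp(sigma * z - 0.5 * sigma**2)
            else:
                noisy = np.repeat(truth, replicates, axis=0)
        for rep in range(replicates):
            records.extend((t, var, float(v)) for t, v in zip(times, noisy[rep]))
    frame = pd.DataFrame(records, columns=["time_days", "variable", "value"])
    return ObservationSet(frame=frame, label=f"{patient.id}/seed={seed}")


@dataclass
class CohortSummary:
    """Pointwise mean and sample SD of each output over a cohort."""

    times: np.ndarray
    mean: dict
    sd: dict
    size: int

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for var in self.mean:
            parts.append(pd.DataFrame({
                "time_days": self.times, "variable": var,
                "mean": self.mean[var], "sd": self.sd[var],
            }))
        return pd.concat(parts, ignore_index=True)


def cohort_summary(trajectories: list[Trajectory]) -> CohortSummary:
    """Mean/SD response profile over a cohort on a common time grid."""
    if not trajectories:
        raise DomainError("empty cohort")
    ref = trajectories[0].times
    for traj in trajectories[1:]:
        if traj.times.shape != ref.shape or not np.allclose(traj.times, ref):
            raise AlignmentError("cohort trajectories must share a common time grid")
    variables = trajectories[0].values.keys()
    mean, sd = {}, {}
    for var in variables:
        stack = np.stack([t.values[var] for t in trajectories])
        mean[var] = stack.mean(axis=0)
        sd[var] = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(ref.size)
    return CohortSummary(times=ref.copy(), mean=mean, sd=sd, size=len(trajectories))


def simulate_cohort(cohort: list[Patient], regimen: DoseRegimen, horizon_days: float = 112.0,
                    output_times=None, engine: str = "fast") -> list[Trajectory]:
    """Simulate every cohort member under a common regimen."""
    return [
        simulate_course(regimen, pk=p.pk, leuko=p.leuko, erythro=p.erythro,
                        horizon_days=horizon_days, output_times=output_times, engine=engine)
        for p in cohort
    ]
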