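"""Study-level validation experiments.

Each function here runs one self-contained computational experiment on the
package — summary statistics of the reported patient table, analytic checks
of the Sobol estimator, parameter-recovery and holdout-prediction studies on
synthetic patients, drug-free stability, and closed-loop 6-TGN control on
the reported patient set.  They are used by the test suite and by
``scripts/acceptance.py``; every quantity is recomputed from scratch at call
time.

Protocol constants (sampling schedules, assay CVs, optimizer budgets) are
the package's study conditions; the methods note discusses how and why they
were chosen.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import qmc

from .cohort import (
    TABLE5_6MP,
    generate_observations,
    load_erythro_fixtures,
    load_leuko_fixtures,
    load_table5,
    make_virtual_cohort,
)
from .estimate import (
    FitSpec,
    ObservationSet,
    SimConfig,
    default_bounds,
    fit_parameters,
    holdout_validate,
)
from .gsa import GsaSpec, SensitivityReport, SobolDesign, run_gsa, total_sobol_indices
from .models import baseline_state
from .nmpc import ControlProblem, run_closed_loop
from .params import Patient
from .simulate import DoseRegimen, simulate_course

#: Front-loaded metabolite sampling (days): twice-weekly draws during the
#: first month of dose-finding, then tapering to the plateau — chosen by
#: Fisher-information design for identifiability of the formation/elimination
#: pair at the 18% assay CV.
METABOLITE_SCHEDULE = (2.0, 3.0, 5.0, 7.0, 9.0, 11.0, 14.0, 17.0, 21.0, 24.0,
                       28.0, 32.0, 36.0, 42.0, 49.0, 56.0, 63.0, 70.0, 84.0,
                       98.0, 105.0, 112.0)

#: Weekly metabolite panel over a 24-week course.
WEEKLY_SCHEDULE = tuple(np.arange(7.0, 169.0, 7.0))

#: Twice-weekly CBC during dose titration (16 weeks).
CBC_SCHEDULE = tuple(np.arange(3.5, 112.1, 3.5))

#: Twice-weekly MCV (from the same CBC draws) over 24 weeks — the slow marker.
MCV_SCHEDULE = tuple(np.arange(3.5, 168.1, 3.5))

STANDARD_REGIMEN = DoseRegimen.daily(75, 112)
LONG_REGIMEN = DoseRegimen.daily(75, 168)

#: Reference patient for the 6-MP synthetic studies (first reported pair).
REFERENCE_6MP = {"k_pt": 38.4, "k_te": 0.0646}


def _seed(master: int, k: int) -> int:
    return (master * 100_003 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# reported-table arithmetic

def table5_statistics() -> dict:
    """Mean/SD of the reported patient-specific (k_pt, k_te) pairs."""
    k_pt = np.array([p[0] for p in TABLE5_6MP])
    k_te = np.array([p[1] for p in TABLE5_6MP])
    return {
        "k_pt_mean": float(k_pt.mean()),
        "k_pt_sd": float(k_pt.std(ddof=1)),
        "k_te_mean": float(k_te.mean()),
        "k_te_sd": float(k_te.std(ddof=1)),
        "n": len(TABLE5_6MP),
    }


#: Reported absolute freezing errors per model (most-sensitive first).
REPORTED_FREEZING_ERRORS = {
    "6mp": (("k_pt", 84.61), ("k_te", 46.36), ("K_t", 0.0003), ("k_e", 0.0002),
            ("k_a", 4.0e-5), ("k_pm", 2.1e-9), ("K_m", 2.1e-9), ("k_me", 0.0)),
    "leuko": (("k_tl", 65.54), ("k_pl", 49.12), ("k_dl", 39.02), ("theta_L", 22.61),
              ("EL_max", 17.60), ("s_l", 2.18), ("ECL_50", 0.25)),
    "mcv": (("k_tr", 76.48), ("k_pr", 50.09), ("k_dr", 20.71), ("theta_R", 11.00),
            ("ER_max", 10.49), ("s_r", 2.48), ("k_m6", 0.71), ("ECR_50", 0.0034)),
}


def freezing_error_percentages(model: str) -> dict:
    """Percent-of-maximum column recomputed from reported absolute errors."""
    names, errors = zip(*REPORTED_FREEZING_ERRORS[model])
    report = SensitivityReport.from_errors(names, np.array(errors))
    return dict(zip(report.table["parameter"], report.table["pct_of_max"]))


def virtual_cohort_sizes() -> dict:
    leuko = make_virtual_cohort(load_table5(), load_leuko_fixtures())
    mcv = make_virtual_cohort(load_table5(), load_erythro_fixtures())
    return {"leukocyte": len(leuko), "mcv": len(mcv)}


# ---------------------------------------------------------------------------
# estimator checks

def sobol_analytic_check(n: int = 4096, seed: int = 0) -> dict:
    """Total indices of Y = 2 Z1 + Z2, Z ~ U(0,1): analytic values 0.8/0.2."""
    sampler = qmc.Sobol(d=4, scramble=True, seed=seed)
    u = sampler.random_base2(int(np.log2(n)))
    design = SobolDesign(A=u[:, :2].copy(), B=u[:, 2:].copy(), names=("z1", "z2"))
    idx = total_sobol_indices(lambda X: 2 * X[:, 0] + X[:, 1], design)
    return {"S_T1": float(idx.S_T[0, 0]), "S_T2": float(idx.S_T[1, 0]), "n": n}


def recovery_study(seed: int = 0, n_noisy: int = 20) -> dict:
    """Recover (k_pt, k_te) from synthetic RBC 6-TGN data.

    Noiseless: 6 sparse samples, errors should be far below 1%.  Noisy: the
    front-loaded 22-sample schedule at the 18% inter-assay CV, per-record
    1/value^2 weights; reports the median relative error over ``n_noisy``
    seeds.
    """
    truth = Patient().with_overrides(REFERENCE_6MP)
    cfg = SimConfig(regimen=STANDARD_REGIMEN)
    bounds = {"k_pt": (10.0, 80.0), "k_te": (0.02, 0.2)}

    obs = generate_observations(truth, STANDARD_REGIMEN,
                                {"x_t": [7.0, 14.0, 28.0, 56.0, 84.0, 112.0]},
                                cv_map={"x_t": 0.0}, seed=_seed(seed, 0))
    spec = FitSpec(free=("k_pt", "k_te"), bounds=bounds, seed=_seed(seed, 1),
                   population=40, generations=60, local_iters=200)
    fit = fit_parameters(obs, spec, cfg)
    noiseless = {name: abs(fit.estimates[name] - REFERENCE_6MP[name]) / REFERENCE_6MP[name]
                 for name in REFERENCE_6MP}

    errors = []
    for k in range(n_noisy):
        obs = generate_observations(truth, STANDARD_REGIMEN,
                                    {"x_t": list(METABOLITE_SCHEDULE)},
                                    seed=_seed(seed, 10 + k))
        frame = obs.frame.copy()
        frame["weight"] = 1.0 / frame["value"] ** 2
        obs = ObservationSet(frame)
        spec = FitSpec(free=("k_pt", "k_te"), bounds=bounds, seed=_seed(seed, 100 + k),
                       population=40, generations=60, local_iters=200)
        fit = fit_parameters(obs, spec, cfg)
        errors.append([abs(fit.estimates[n] - REFERENCE_6MP[n]) / REFERENCE_6MP[n]
                       for n in ("k_pt", "k_te")])
    errors = np.asarray(errors)
    return {
        "noiseless_max_rel_error": max(noiseless.values()),
        "noisy_median_rel_error": float(np.median(errors)),
        "noisy_median_k_pt": float(np.median(errors[:, 0])),
        "noisy_median_k_te": float(np.median(errors[:, 1])),
        "n_seeds": n_noisy,
    }


def baseline_stability(days: float = 365.0) -> dict:
    """Drug-free relative drift from the computed steady state, all systems."""
    patient = Patient()
    traj = simulate_course(DoseRegimen(), pk=patient.pk, leuko=patient.leuko,
                           erythro=patient.erythro, horizon_days=days, engine="lsoda")
    leuko0 = baseline_state(patient.leuko)
    ery0 = baseline_state(patient.erythro)
    drift = {
        "pk": float(np.max(np.abs(traj.values["x_t"])) + np.max(np.abs(traj.values["x_m"]))),
        "leuko": float(np.max(np.abs(traj.values["L"] - leuko0.L)) / leuko0.L),
        "erythro": float(np.max(np.abs(traj.values["M"] - ery0.M)) / ery0.M),
    }
    drift["max_relative"] = max(drift["leuko"], drift["erythro"], drift["pk"])
    return drift


# ---------------------------------------------------------------------------
# control and prediction studies

def tgn_control_study(seed: int = 0) -> dict:
    """Closed-loop 6-TGN titration for each reported patient.

    Reports, per patient, the ratio of the final tracking error |x_t(75)-300|
    to the initial error (300, from the drug-free start), whether all input
    constraints held, and the structural exposure ceiling f_tgn*k_pt/k_te.
    """
    results = []
    for fixture in load_table5():
        patient = fixture.to_patient()
        problem = ControlProblem(mode="tgn", seed=_seed(seed, 7))
        trace = run_closed_loop(patient, problem)
        x_end = float(trace.trajectory.values["x_t"][-1])
        initial_error = abs(300.0 - 0.0)
        final_error = abs(300.0 - x_end)
        f_tgn = 1.0 - patient.pk.e / patient.pk.e_max
        results.append({
            "patient": fixture.id,
            "x_t_final": x_end,
            "error_ratio": final_error / initial_error,
            "constraints_ok": bool(trace.check_constraints()),
            "exposure_ceiling": f_tgn * patient.pk.k_pt / patient.pk.k_te,
        })
    return {
        "patients": results,
        "max_error_ratio": max(r["error_ratio"] for r in results),
        "all_constraints_ok": all(r["constraints_ok"] for r in results),
        "n_within_10pct": sum(r["error_ratio"] < 0.10 for r in results),
    }


def holdout_study(model: str, seed: int = 0, n_seeds: int = 20) -> dict:
    """Forward-prediction SSE gap (median over seeds) for one model.

    6-MP: both metabolite panels (18%/22% CV, weekly over 24 weeks); WBC:
    twice-weekly CBC (10% CV); MCV: twice-weekly MCV-shift over 24 weeks
    (1 fL additive).  Fits use the earliest two-thirds of records.
    """
    gaps = []
    for k in range(n_seeds):
        if model == "6mp":
            patient = Patient().with_overrides(REFERENCE_6MP)
            regimen, cfg = LONG_REGIMEN, SimConfig(regimen=LONG_REGIMEN)
            schedule = {"x_t": list(WEEKLY_SCHEDULE), "x_m": list(WEEKLY_SCHEDULE)}
            free = ("k_pt", "k_te")
            budget = dict(population=24, generations=30, local_iters=100)
        elif model == "wbc":
            patient = load_leuko_fixtures()[0].to_patient()
            regimen = STANDARD_REGIMEN
            cfg = SimConfig(regimen=regimen, dt_pk=0.04, dt_pd=0.15)
            schedule = {"L": list(CBC_SCHEDULE)}
            free = ("EL_max", "k_dl")
            budget = dict(population=20, generations=25, local_iters=60)
        elif model == "mcv":
            patient = load_erythro_fixtures()[0].to_patient()
            regimen = LONG_REGIMEN
            cfg = SimConfig(regimen=regimen, dt_pk=0.04, dt_pd=0.2)
            schedule = {"dmcv": list(MCV_SCHEDULE)}
            free = ("k_m6", "k_tr")
            budget = dict(population=20, generations=25, local_iters=60)
        else:
            raise ValueError(model)
        obs = generate_observations(patient, regimen, schedule, seed=_seed(seed, 200 + k))
        spec = FitSpec(free=free, bounds=default_bounds(free, Patient()),
                       seed=_seed(seed, 300 + k), **budget)
        gaps.append(holdout_validate(obs, spec, cfg).relative_gap)
    gaps = np.asarray(gaps)
    return {"median_gap": float(np.median(gaps)), "max_gap": float(gaps.max()),
            "n_seeds": n_seeds}


def reduction_study(seed: int = 0, n_seeds: int = 5, n: int = 1000) -> dict:
    """Sensitive/redundant classification of the 6-MP model over seeds."""
    runs = []
    for k in range(n_seeds):
        report = run_gsa(GsaSpec(output="x_t", n=n, seed=_seed(seed, 400 + k)))
        runs.append({"sensitive": report.sensitive, "redundant": report.redundant})
    match = sum(set(r["sensitive"]) == {"k_pt", "k_te"} for r in runs)
    return {"runs": runs, "n_matching": match, "n_seeds": n_seeds,
            "majority": match > n_seeds / 2}
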