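"""Receding-horizon dose optimization: cost, constraints, closed loop."""

import warnings

import numpy as np
import pytest

from sixmp.errors import ConfigError
from sixmp.nmpc import (
    ControlProblem,
    _predict_targets,
    initial_dose_from_tpmt,
    nmpc_cost,
    run_closed_loop,
    solve_step,
    steady_state_tgn,
)
from sixmp.models import SixMPState, baseline_state
from sixmp.params import Patient


def _baseline_state(patient):
    return (SixMPState(), baseline_state(patient.leuko), baseline_state(patient.erythro))


class TestControlProblem:
    def test_defaults(self):
        prob = ControlProblem(mode="tgn")
        assert prob.references["x_t"] == 300.0
        assert prob.weights["x_t"] == pytest.approx(1.0 / 300.0**2)
        assert prob.n_intervals == 5

    @pytest.mark.parametrize("kwargs", [
        {"mode": "bogus"}, {"window_days": 70.0}, {"u_min": -1.0},
        {"u_max": 10.0, "u_min": 20.0}, {"horizon_intervals": 0},
    ])
    def test_invalid_problems_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ControlProblem(**kwargs)


class TestNmpcCost:
    def test_single_interval_squared_error(self):
        """One interval, unit weight: cost is the squared endpoint error."""
        patient = Patient()
        prob = ControlProblem(mode="tgn", window_days=15.0, weights={"x_t": 1.0})
        state = _baseline_state(patient)
        pred = _predict_targets(patient, prob, state, 0.0, np.array([75.0]))["x_t"][0]
        prob_shifted = ControlProblem(mode="tgn", window_days=15.0, weights={"x_t": 1.0},
                                      references={"x_t": pred - 10.0})
        assert nmpc_cost([75.0], patient, prob_shifted, state) == pytest.approx(100.0, rel=1e-9)

    def test_two_target_cost_matches_hand_sum(self):
        """WBC+MCV mode on a 2-interval toy problem equals the hand-weighted
        two-target sum of squared endpoint errors."""
        patient = Patient()
        prob = ControlProblem(mode="wbc_mcv", window_days=30.0)
        state = _baseline_state(patient)
        seq = np.array([60.0, 90.0])
        preds = _predict_targets(patient, prob, state, 0.0, seq)
        expected = sum(
            prob.weights[t] * np.sum((preds[t] - prob.references[t]) ** 2)
            for t in ("L", "dmcv"))
        assert nmpc_cost(seq, patient, prob, state) == pytest.approx(expected, rel=1e-12)

    def test_reference_at_prediction_gives_zero_cost(self):
        patient = Patient()
        prob = ControlProblem(mode="tgn", window_days=15.0)
        state = _baseline_state(patient)
        pred = _predict_targets(patient, prob, state, 0.0, np.array([75.0]))["x_t"][0]
        prob_met = ControlProblem(mode="tgn", window_days=15.0, references={"x_t": pred})
        assert nmpc_cost([75.0], patient, prob_met, state) == 0.0


class TestSolveStep:
    def test_met_target_keeps_previous_dose(self):
        """If holding the previous dose already achieves the reference the
        stationary plan has zero cost and the first move is unchanged."""
        patient = Patient()
        probe = ControlProblem(mode="tgn", window_days=75.0)
        state = _baseline_state(patient)
        preds = _predict_targets(patient, probe, state, 0.0, np.full(5, 75.0))["x_t"]
        prob = ControlProblem(mode="tgn", window_days=75.0,
                              references={"x_t": float(preds[-1])},
                              weights={"x_t": 0.0})  # indifferent cost
        sol = solve_step(patient, prob, current_state=state, previous_dose=75.0)
        assert sol.first_dose == 75.0
        assert sol.cost == 0.0

    def test_zero_slew_bound_pins_the_dose(self):
        patient = Patient()
        prob = ControlProblem(mode="tgn", du_max=0.0)
        sol = solve_step(patient, prob, previous_dose=40.0)
        assert np.allclose(sol.sequence, 40.0)

    def test_underexposed_patient_gets_a_dose_increase(self):
        """Far below the 6-TGN target with slack constraints, the first move
        exceeds the previous dose (dose -> exposure response is monotone)."""
        # quasi-linear conversion so the dose response is steep
        patient = Patient().with_overrides({"K_t": 1e8, "k_pt": 400.0})
        prob = ControlProblem(mode="tgn", du_max=150.0)
        sol = solve_step(patient, prob, previous_dose=10.0)
        assert sol.first_dose > 10.0

    def test_planned_sequences_respect_bounds_and_slew(self):
        patient = Patient()
        prob = ControlProblem(mode="tgn", seed=3)
        sol = solve_step(patient, prob, previous_dose=75.0)
        u = np.concatenate([[75.0], sol.sequence])
        assert np.all(sol.sequence >= prob.u_min) and np.all(sol.sequence <= prob.u_max)
        assert np.all(np.abs(np.diff(u)) <= prob.du_max + 1e-9)


class TestClosedLoop:
    def test_tpmt_directionality_of_optimal_dosing(self):
        """Low-TPMT patients need less than the 75 mg/day standard to sit at
        the 6-TGN target; high-TPMT patients need more."""
        prob = ControlProblem(mode="tgn", seed=1)
        low = Patient(pk=Patient().pk.replace(e=0.001), id="low-tpmt")
        high = Patient(pk=Patient().pk.replace(e=20.0), id="high-tpmt")
        trace_low = run_closed_loop(low, prob)
        trace_high = run_closed_loop(high, prob)
        assert trace_low.applied_doses.mean() < 75.0 < trace_high.applied_doses.mean()
        assert trace_low.check_constraints() and trace_high.check_constraints()
        # the low-TPMT patient can actually reach the 300 target
        assert trace_low.trajectory.values["x_t"][-1] == pytest.approx(300.0, rel=0.05)

    def test_zero_weight_problem_holds_the_initial_dose(self):
        prob = ControlProblem(mode="tgn", weights={"x_t": 0.0}, seed=0)
        trace = run_closed_loop(Patient(), prob)
        assert np.allclose(trace.applied_doses, prob.initial_dose)

    def test_wbc_titration_with_hard_floor_meets_band(self):
        """Floor-mode leukocyte titration keeps the count above 95% of the
        3e9 cells/L target after the first correction and lands near it."""
        prob = ControlProblem(mode="wbc", seed=2, wbc_floor=2.9e9, floor_weight=1e4)
        trace = run_closed_loop(Patient(), prob)
        L = trace.trajectory.values["L"]
        t = trace.trajectory.times
        assert L[t >= prob.interval_days].min() >= 0.95 * 3e9
        assert L[-1] == pytest.approx(3e9, rel=0.15)
        assert trace.check_constraints()

    def test_default_wbc_mode_beats_open_loop_standard_dosing(self):
        """Even without the floor, predictive dosing keeps the nadir well
        above the open-loop 75 mg/day nadir while tracking the target."""
        from sixmp.simulate import DoseRegimen, simulate_course

        prob = ControlProblem(mode="wbc", seed=2)
        trace = run_closed_loop(Patient(), prob)
        L = trace.trajectory.values["L"]
        open_loop = simulate_course(DoseRegimen.daily(75, 75), horizon_days=75.0,
                                    engine="fast")
        assert L.min() > open_loop.values["L"].min()
        assert L[-1] == pytest.approx(3e9, rel=0.15)
        assert trace.check_constraints()


class TestInitialDose:
    def test_bisection_reproduces_window_midpoint(self):
        """On a model whose therapeutic window is reachable, re-simulating the
        returned dose reproduces the 317.5 midpoint within 1%."""
        boosted = Patient().with_overrides({"k_pt": 60.0})
        dose = initial_dose_from_tpmt(13.0, 26.0, average_model=boosted)
        ss = steady_state_tgn(boosted.pk.replace(e=13.0, e_max=26.0), dose)
        assert ss == pytest.approx(317.5, rel=1e-2)

    def test_lower_tpmt_needs_lower_dose(self):
        boosted = Patient().with_overrides({"k_pt": 60.0})
        d_null = initial_dose_from_tpmt(0.0, 26.0, average_model=boosted)
        d_mid = initial_dose_from_tpmt(13.0, 26.0, average_model=boosted)
        assert d_null < d_mid

    def test_unreachable_window_clips_to_bound_with_warning(self):
        # full methylation: no 6-TGN can form at any dose
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            dose = initial_dose_from_tpmt(26.0, 26.0)
        assert dose == 150.0
        assert any("unreachable" in str(w.message) for w in caught)
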