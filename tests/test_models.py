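"""Unit and property tests for the three ODE systems and their rate laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sixmp.errors import (
    DomainError,
    InfeasibleBaselineError,
    InvalidActivityError,
    SingularStateError,
)
from sixmp.models import (
    ErythroState,
    LeukoState,
    SixMPState,
    baseline_state,
    equilibrium_circulating,
    erythro_rhs,
    feedback_rate,
    hill_effect,
    leuko_rhs,
    sixmp_rhs,
    tpmt_partition,
)
from sixmp.params import ErythroParams, LeukoParams, SixMPParams, dose_mg_to_pmol


class TestTpmtPartition:
    @pytest.mark.parametrize(
        "e, e_max, expected",
        [(13.0, 26.0, (0.5, 0.5)), (0.0, 26.0, (0.0, 1.0)), (26.0, 26.0, (1.0, 0.0))],
    )
    def test_reference_splits(self, e, e_max, expected):
        assert tpmt_partition(e, e_max) == pytest.approx(expected)

    @pytest.mark.parametrize("e, e_max", [(27.0, 26.0), (-1.0, 26.0), (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_activity_rejected(self, e, e_max):
        with pytest.raises(InvalidActivityError):
            tpmt_partition(e, e_max)

    @given(st.floats(0.0, 1.0), st.floats(1e-3, 1e3))
    @settings(max_examples=50, derandomize=True)
    def test_fractions_partition_unity(self, frac, e_max):
        f_memp, f_tgn = tpmt_partition(frac * e_max, e_max)
        assert f_memp + f_tgn == pytest.approx(1.0)
        assert 0.0 <= f_memp <= 1.0


class TestSixmpRhs:
    def test_empty_system_is_at_equilibrium(self):
        d = sixmp_rhs(SixMPState(), SixMPParams(), dose_rate=0.0)
        assert d.as_array() == pytest.approx(np.zeros(4))

    def test_michaelis_menten_saturation_limit(self):
        p = SixMPParams()
        state = SixMPState(x_p=1e15, x_t=50.0)
        d = sixmp_rhs(state, p)
        _, f_tgn = tpmt_partition(p.e, p.e_max)
        assert d.x_t == pytest.approx(f_tgn * p.k_pt - p.k_te * 50.0, rel=1e-6)

    def test_negative_state_rejected(self):
        with pytest.raises(DomainError):
            sixmp_rhs(SixMPState(x_g=-1.0), SixMPParams())

    def test_single_bolus_matches_fine_euler_oracle(self):
        """Adaptive integration of 6-TGN after one oral bolus agrees with a
        brute-force explicit Euler solution at dt = 1e-4 days to 0.1%."""
        from sixmp.simulate import DoseRegimen, simulate_course

        p = SixMPParams()  # e/e_max = 13/26 -> f_tgn = 0.5
        dose = dose_mg_to_pmol(75.0)
        dt = 1e-4
        n = int(round(28.0 / dt))
        f_memp, f_tgn = tpmt_partition(p.e, p.e_max)
        x_g, x_p, x_t = dose, 0.0, 0.0
        checkpoints = {1.0: None, 7.0: None, 28.0: None}
        steps_per_day = int(round(1.0 / dt))
        for i in range(n):
            dx_g = -p.k_a * x_g
            dx_p = p.k_a * x_g - p.k_e * x_p
            dx_t = f_tgn * p.k_pt * x_p / (p.K_t + x_p) - p.k_te * x_t
            x_g += dt * dx_g
            x_p += dt * dx_p
            x_t += dt * dx_t
            day = (i + 1) / steps_per_day
            if (i + 1) % steps_per_day == 0 and float(day) in checkpoints:
                checkpoints[float(day)] = x_t
        traj = simulate_course(DoseRegimen(((0.0, 75.0),)), pk=p, horizon_days=28.0,
                               output_times=np.array([1.0, 7.0, 28.0]), engine="lsoda")
        for t, oracle in zip([1.0, 7.0, 28.0], traj.values["x_t"]):
            assert oracle == pytest.approx(checkpoints[t], rel=1e-3)


class TestFeedbackAndHill:
    def test_hill_midpoint_and_saturation(self):
        assert feedback_rate(6e9, 0.314, 6e9, 2.0) == pytest.approx(0.157)
        assert feedback_rate(1e-6, 0.314, 6e9, 2.0) == pytest.approx(0.314)

    def test_calibrated_baseline_proliferation(self):
        lp = LeukoParams()
        assert feedback_rate(6e9, lp.k_pl, lp.theta_L, lp.s_l) == pytest.approx(0.157)

    @given(st.floats(1e6, 1e12), st.floats(1e6, 1e12))
    @settings(max_examples=50, derandomize=True)
    def test_feedback_strictly_decreasing(self, c1, c2):
        lo, hi = sorted([c1, c2])
        if hi > lo:
            assert feedback_rate(hi, 0.314, 6e9, 2.0) < feedback_rate(lo, 0.314, 6e9, 2.0)

    def test_hill_effect_zero_and_half_maximum(self):
        assert hill_effect(0.0, 0.2, 84.0, 1.0) == 0.0
        assert hill_effect(84.0, 0.2, 84.0, 1.0) == pytest.approx(0.1)
        lp = LeukoParams()
        assert hill_effect(lp.ECL_50, lp.EL_max, lp.ECL_50, lp.h_l) == pytest.approx(lp.EL_max / 2)

    @given(st.floats(0.0, 1e4), st.floats(0.0, 1e4))
    @settings(max_examples=50, derandomize=True)
    def test_hill_effect_monotone(self, x1, x2):
        lo, hi = sorted([x1, x2])
        assert hill_effect(hi, 0.2, 84.0, 1.5) >= hill_effect(lo, 0.2, 84.0, 1.5)


class TestLeukoRhs:
    def test_baseline_is_steady(self):
        lp = LeukoParams()
        state = baseline_state(lp, target_circulating=6e9)
        d = leuko_rhs(state, lp, x_t=0.0).as_array()
        assert np.all(np.abs(d) < 1e-9 * np.abs(state.as_array()))

    def test_net_kill_when_drug_overwhelms_feedback(self):
        lp = LeukoParams()
        state = baseline_state(lp)
        d = leuko_rhs(state, lp, x_t=100 * lp.ECL_50)
        assert d.S_L < 0

    def test_nadir_delayed_by_transit_chain(self):
        """A step of 6-TGN from zero depresses circulating counts only after
        the maturation delay: the nadir lies beyond 0.5 * 3/k_tl days."""
        from sixmp import _fast

        lp = LeukoParams()
        y0 = baseline_state(lp).as_array()[None, :]
        dt = 0.1
        n = int(round(60.0 / dt))
        xt = np.full((1, 2 * n + 1), 300.0)
        traj = _fast.pd_curves("leuko", lp.to_dict(), xt, dt, y0)
        nadir_day = dt * np.argmin(traj[0, :, 4])
        assert nadir_day > 0.5 * 3.0 / lp.k_tl


class TestErythroRhs:
    def test_baseline_mcv_is_steady(self):
        ep = ErythroParams()
        state = baseline_state(ep)
        d = erythro_rhs(state, ep, x_t=0.0)
        assert d.M == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.abs(d.as_array()) < 1e-9 * np.maximum(np.abs(state.as_array()), 1.0))

    def test_zero_rbc_is_singular(self):
        ep = ErythroParams()
        with pytest.raises(SingularStateError):
            erythro_rhs(ErythroState(1e10, 1e10, 1e10, 1e10, 0.0, 85.0), ep)

    def test_mcv_plateau_matches_closed_form(self):
        """Constant 6-TGN exposure of 158 drives the MCV shift to the fixed
        point k_m6 * 158 / k_dr (the calibrated ~8 fL plateau) within 1%."""
        from sixmp import _fast

        ep = ErythroParams()
        y0 = baseline_state(ep).as_array()[None, :]
        dt = 0.25
        n = int(round(1500.0 / dt))
        xt = np.full((1, 2 * n + 1), 158.0)
        traj = _fast.pd_curves("erythro", ep.to_dict(), xt, dt, y0)
        plateau = traj[0, -1, 5] - ep.M_in
        expected = ep.k_m6 * 158.0 / ep.k_dr
        assert plateau == pytest.approx(expected, rel=1e-2)
        assert expected == pytest.approx(8.0, rel=1e-9)

    def test_mcv_fixed_point_linear_in_release_volume(self):
        ep = ErythroParams()
        doubled = ep.replace(M_in=2 * ep.M_in)
        assert baseline_state(doubled).M == pytest.approx(2 * baseline_state(ep).M)


class TestBaselineState:
    def test_leuko_residual_norm(self):
        lp = LeukoParams()
        state = baseline_state(lp, target_circulating=6e9)
        assert state.L == pytest.approx(6e9)
        d = leuko_rhs(state, lp).as_array()
        assert np.linalg.norm(d / np.maximum(np.abs(state.as_array()), 1.0)) < 1e-8

    def test_transit_chain_equalizes(self):
        state = baseline_state(LeukoParams())
        assert state.S_L == state.C_L1 == state.C_L2 == state.C_L3
        ery = baseline_state(ErythroParams())
        assert ery.S_R == ery.C_R1 == ery.C_R2 == ery.C_R3
        assert ery.M == ErythroParams().M_in

    def test_infeasible_when_proliferation_cannot_cover_demand(self):
        lp = LeukoParams().replace(k_pl=0.1)  # below k_tl + k_sl
        with pytest.raises(InfeasibleBaselineError):
            baseline_state(lp)

    def test_inconsistent_target_rejected(self):
        with pytest.raises(InfeasibleBaselineError):
            baseline_state(LeukoParams(), target_circulating=5e9)

    def test_equilibrium_closed_form(self):
        lp = LeukoParams()
        L_eq = equilibrium_circulating(lp)
        assert feedback_rate(L_eq, lp.k_pl, lp.theta_L, lp.s_l) == pytest.approx(
            lp.k_tl + lp.k_sl, rel=1e-12)


class TestMonotonicityInTpmt:
    def test_higher_tpmt_suppresses_tgn_and_raises_memp(self):
        """Patients with higher TPMT activity shunt 6-MP away from the active
        6-TGN pathway into methylated metabolites."""
        from sixmp.simulate import DoseRegimen, simulate_course

        reg = DoseRegimen.daily(75, 150)
        results = []
        for e in (5.0, 13.0, 21.0):
            pk = SixMPParams().replace(e=e)
            traj = simulate_course(reg, pk=pk, horizon_days=150.0, engine="fast")
            results.append((traj.values["x_t"][-1], traj.values["x_m"][-1]))
        x_t_vals, x_m_vals = zip(*results)
        assert x_t_vals[0] > x_t_vals[1] > x_t_vals[2]
        assert x_m_vals[0] < x_m_vals[1] < x_m_vals[2]


class TestParamValidation:
    def test_positive_invariants_enforced(self):
        with pytest.raises(DomainError):
            SixMPParams(k_a=-1.0)
        with pytest.raises(DomainError):
            LeukoParams(theta_L=0.0)
        with pytest.raises(InvalidActivityError):
            SixMPParams(e=30.0)

    def test_dict_round_trip(self):
        p = SixMPParams().replace(k_pt=38.4)
        assert SixMPParams.from_dict(p.to_dict()) == p
        with pytest.raises(DomainError):
            SixMPParams.from_dict({"bogus": 1.0})
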