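"""Forward model: algebraic pieces, implicit CO solve, trajectory invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemovol import (
    InputSchedule,
    PhysiologicalInfeasibilityError,
    Segment,
    SubjectContext,
    baseline_equilibrium,
    fluid_exchange_rate,
    simulate_subject,
    solve_cardiac_output,
    state_derivatives,
    target_blood_volume,
)
from hemovol.model import co_residual


class TestTargetBloodVolume:
    @pytest.mark.parametrize(
        "cum_u, cum_v, a_u, a_v, expected",
        [
            (2.0, 0.0, 1.0, 1.0, 1.0),
            (0.0, 1.0, 1.0, 0.25, -0.8),
            (2.0, 1.0, 1.0, 0.25, 0.2),
        ],
    )
    def test_partition_arithmetic(self, cum_u, cum_v, a_u, a_v, expected):
        assert target_blood_volume(cum_u, cum_v, a_u, a_v) == pytest.approx(expected, abs=1e-15)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            target_blood_volume(np.nan, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            target_blood_volume(-0.1, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            target_blood_volume(1.0, 0.0, -1.0, 1.0)

    @given(
        cum_u=st.floats(0, 10), cum_v=st.floats(0, 10),
        a_u=st.floats(-0.9, 6), a_v=st.floats(-0.9, 6),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_each_input(self, cum_u, cum_v, a_u, a_v):
        r = target_blood_volume(cum_u, cum_v, a_u, a_v)
        r2 = target_blood_volume(2 * cum_u, 2 * cum_v, a_u, a_v)
        assert r2 == pytest.approx(2 * r, rel=1e-12, abs=1e-12)


class TestFluidExchange:
    def test_sign_convention_and_equilibrium(self):
        # negative u_ex is subtracted from the volume balance, pushing
        # dVB toward the target
        assert fluid_exchange_rate(1.0, 0.0, 0.1) == pytest.approx(-0.1)
        assert fluid_exchange_rate(0.5, 0.5, 0.3) == 0.0
        assert fluid_exchange_rate(-0.5, 0.0, 0.2) == pytest.approx(0.1)

    def test_requires_positive_gain(self):
        with pytest.raises(ValueError):
            fluid_exchange_rate(1.0, 0.0, 0.0)


class TestCardiacOutputSolve:
    def test_explicit_case_when_venous_coupling_absent(self, mode_params):
        # gk_over_B = 0 makes the equation explicit:
        # CO = HR/A * log(G*(V_B - eta*V_B0) + 1)
        theta = mode_params.replace(gk_over_B=0.0, A_over_Es=0.0, A=10.0,
                                    g_over_BCs=1.0, eta=0.0)
        v_b = np.e - 1.0
        co = solve_cardiac_output(theta, hr=60.0, tpr=20.0, v_b=v_b, v_b0=1.0)
        assert co == pytest.approx(6.0, rel=1e-9)

    def test_matches_bracketed_bisection_oracle(self, mode_params):
        theta = mode_params.replace(A=12.0, A_over_Es=0.005, gk_over_B=0.008,
                                    g_over_BCs=2.0, eta=0.5)
        hr, tpr, v_b, v_b0 = 90.0, 20.0, 2.0, 2.4

        def f(co):
            c1 = hr / (theta.A + theta.A_over_Es * hr * tpr)
            arg = theta.g_over_BCs * (v_b - theta.eta * v_b0) + 1.0 - theta.gk_over_B * tpr * co
            return c1 * np.log(arg) - co

        lo, hi = 1e-9, (theta.g_over_BCs * (v_b - theta.eta * v_b0) + 1.0) / (
            theta.gk_over_B * tpr
        ) * (1 - 1e-12)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        co = solve_cardiac_output(theta, hr, tpr, v_b, v_b0)
        assert co == pytest.approx(0.5 * (lo + hi), abs=1e-9)
        assert co_residual(theta, co, hr, tpr, v_b, v_b0) < 1e-8

    def test_infeasible_state_raises(self, mode_params):
        # stressed volume so low the log argument cannot stay positive
        with pytest.raises(PhysiologicalInfeasibilityError):
            solve_cardiac_output(mode_params, hr=90.0, tpr=20.0, v_b=0.5, v_b0=2.37)
        with pytest.raises(PhysiologicalInfeasibilityError):
            solve_cardiac_output(mode_params, hr=90.0, tpr=-1.0, v_b=2.4, v_b0=2.37)

    def test_baseline_equilibrium_closed_form_consistent(self, mode_params):
        co0, map0 = baseline_equilibrium(mode_params, v_b0=2.37, hr=90.0)
        assert map0 == mode_params.MAP_target
        co = solve_cardiac_output(mode_params, 90.0, map0 / co0, 2.37, 2.37)
        assert co == pytest.approx(co0, rel=1e-9)


class TestStateDerivatives:
    def test_volume_balance_arithmetic(self, mode_params, baseline_context):
        sched = InputSchedule([Segment(0, 10, 2.0, 0.0)], horizon=20)
        # state chosen so u_ex = -K_p*(r_BV - dVB) = -0.25*(0 - 2) = 0.5
        state = np.array([2.0, 0.0, 0.0, 0.0])
        d = state_derivatives(5.0, state, mode_params, baseline_context, sched)
        assert d[0] == pytest.approx(2.0 - 0.0 - 0.5)
        assert d[2] == 2.0 and d[3] == 0.0

    def test_pressure_regulation_equilibrium(self, mode_params, baseline_context):
        sched = InputSchedule([], horizon=20)
        d = state_derivatives(5.0, np.zeros(4), mode_params, baseline_context, sched)
        # at baseline MAP equals the set point and dTPR = 0
        assert d[1] == pytest.approx(0.0, abs=1e-9)

    def test_composed_form_matches_symbolic_substitution(self, mode_params, baseline_context):
        # substituting the exchange law into the balance gives
        # dVB' = u - v + K_p*(r_BV - dVB)
        sched = InputSchedule([Segment(0, 10, 0.5, 0.2)], horizon=20)
        state = np.array([-0.3, 0.1, 1.0, 0.8])
        d = state_derivatives(4.0, state, mode_params, baseline_context, sched)
        r_bv = 1.0 / (1 + mode_params.alpha_u) - 0.8 / (1 + mode_params.alpha_v)
        expected = 0.5 - 0.2 + mode_params.K_p * (r_bv - (-0.3))
        assert d[0] == pytest.approx(expected, rel=1e-12)


class TestSimulateSubject:
    def test_equilibrium_preserved_without_inputs(self, mode_params, baseline_context,
                                                  sampling_grid):
        sched = InputSchedule([], horizon=180)
        res = simulate_subject(mode_params, baseline_context, sched, sampling_grid)
        assert np.allclose(res.vb, baseline_context.V_B0, atol=1e-7)
        assert np.allclose(res.co, baseline_context.CO_0, atol=1e-6)
        assert np.allclose(res.map, baseline_context.MAP_0, atol=1e-5)

    def test_map_identity_everywhere(self, mode_params, baseline_context,
                                     hemorrhage_schedule, sampling_grid):
        res = simulate_subject(mode_params, baseline_context, hemorrhage_schedule, sampling_grid)
        np.testing.assert_allclose(res.map, res.co * res.tpr, rtol=0, atol=1e-12)
        assert res.max_co_residual < 1e-8

    def test_finished_bleed_settles_at_partitioned_volume(self, mode_params, baseline_context,
                                                          hemorrhage_schedule):
        # steady state of the volume kinetics: dVB(inf) = -V_tot/(1+alpha_v)
        grid = np.array([0.0, 15.0, 60.0, 120.0, 180.0])
        res = simulate_subject(mode_params, baseline_context, hemorrhage_schedule, grid)
        expected = -1.0 / (1.0 + mode_params.alpha_v)
        assert res.delta_vb[-1] == pytest.approx(expected, abs=1e-6)

    def test_fast_path_matches_adaptive(self, mode_params, baseline_context,
                                        hemorrhage_schedule, sampling_grid):
        ref = simulate_subject(mode_params, baseline_context, hemorrhage_schedule, sampling_grid)
        fast = simulate_subject(mode_params, baseline_context, hemorrhage_schedule,
                                sampling_grid, method="fast", step=0.25)
        for name in ("vb", "co", "map", "tpr"):
            a, b = getattr(ref, name), getattr(fast, name)
            assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 1e-6

    def test_rejects_bad_grid(self, mode_params, baseline_context, hemorrhage_schedule):
        with pytest.raises(ValueError):
            simulate_subject(mode_params, baseline_context, hemorrhage_schedule,
                             np.array([0.0, 0.0, 5.0]))
        with pytest.raises(ValueError):
            simulate_subject(mode_params, baseline_context, hemorrhage_schedule,
                             np.array([0.0, 400.0]))
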