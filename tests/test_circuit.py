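"""Vessel mechanics and flow-circuit unit tests."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aslrh import CuffProtocol, SubjectParams, simulate
from aslrh.circuit import (
    CalibrationError,
    CircuitState,
    arteriolar_RV,
    circuit_rhs,
    elastic_tension,
    muscular_tension,
    poiseuille_resistance,
    pressure_from_radius,
    radius_from_pressure,
    segment_flows,
    wall_thickness,
)
from aslrh.simulator import baseline_state

UM = 1e-4  # cm per µm


class TestPoiseuille:
    def test_popliteal_standard_value(self, constants):
        """The standard popliteal geometry gives 0.013 mmHg·min/mL."""
        R = poiseuille_resistance(constants.r_p, constants.l_p, constants.eta_b)
        assert R / 60.0 == pytest.approx(0.013, abs=5e-5)

    def test_pressure_drop_at_resting_flow(self, constants):
        """R_p × Q_r reproduces the 1.8775 mmHg popliteal drop."""
        R = poiseuille_resistance(constants.r_p, constants.l_p, constants.eta_b)
        assert R * constants.Q_r == pytest.approx(1.8775, abs=1e-4)

    def test_fourth_power_scaling(self, constants):
        R1 = poiseuille_resistance(0.1, 10.0, constants.eta_b)
        R2 = poiseuille_resistance(0.2, 10.0, constants.eta_b)
        assert R1 / R2 == pytest.approx(16.0, rel=1e-12)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            poiseuille_resistance(*bad)


class TestWallMechanics:
    def test_thickness_at_unstressed_radius(self, constants):
        assert wall_thickness(constants.r_a0, constants) == pytest.approx(
            constants.h_a0, rel=1e-12
        )

    def test_thickness_at_128um(self, constants):
        # direct evaluation of the wall-volume law at 128 µm
        assert wall_thickness(128 * UM, constants) == pytest.approx(
            16.079838978255395 * UM, rel=1e-9
        )

    def test_thickness_vanishes_monotonically_at_large_radius(self, constants):
        r = np.linspace(50, 2000, 300) * UM
        h = np.array([wall_thickness(ri, constants) for ri in r])
        assert np.all(np.diff(h) < 0) and 0 < h[-1] < 2 * UM

    @given(st.floats(min_value=20, max_value=500))
    def test_wall_cross_section_conserved(self, r_um):
        """(r+h)² − r² is independent of r: the wall area is conserved."""
        from aslrh.constants import ModelConstants

        c = ModelConstants()
        r = r_um * UM
        h = wall_thickness(r, c)
        area0 = (c.r_a0 + c.h_a0) ** 2 - c.r_a0**2
        assert (r + h) ** 2 - r**2 == pytest.approx(area0, rel=1e-10)

    def test_elastic_tension_resting_value(self, constants):
        """At the unstressed radius T_e = (σ1 − σ2)·h_a0 < 0."""
        assert elastic_tension(constants.r_a0, constants) == pytest.approx(
            -0.1033, rel=1e-9
        )

    def test_elastic_tension_increasing_above_unstressed(self, constants):
        r = np.linspace(75, 250, 200) * UM
        te = np.array([elastic_tension(ri, constants) for ri in r])
        assert np.all(np.diff(te) > 0)

    def test_elastic_tension_root(self, constants):
        """T_e = 0 where the exponential bracket vanishes."""
        r_zero = constants.r_a0 * (
            1 + math.log(constants.sigma_2 / constants.sigma_1) / constants.k_e
        )
        assert abs(elastic_tension(r_zero, constants)) < 1e-12

    def test_muscular_tension_peak_and_width(self, constants):
        assert muscular_tension(constants.r_am, constants) == pytest.approx(
            constants.T_m0, rel=1e-12
        )
        assert muscular_tension(constants.r_at, constants) == pytest.approx(
            constants.T_m0 / math.e, rel=1e-12
        )

    @given(st.floats(min_value=1.0, max_value=60.0))
    def test_muscular_tension_symmetric(self, delta_um):
        from aslrh.constants import ModelConstants

        c = ModelConstants()
        d = delta_um * UM
        assert muscular_tension(c.r_am + d, c) == pytest.approx(
            muscular_tension(c.r_am - d, c), rel=1e-12
        )


class TestTensionBalance:
    # radii avoid the bistable band near the active-tension bump
    # (r ≈ 127–150 µm at high activation, where the balance has three
    # equilibria and an inverse solve is not well posed)
    @pytest.mark.parametrize("r_um", [40.0, 64.0, 90.0, 180.0])
    @pytest.mark.parametrize("A", [0.0, 0.3, 0.71, 1.0])
    def test_forward_inverse_round_trip(self, constants, r_um, A):
        P_a = pressure_from_radius(r_um * UM, A, constants)
        r_back = radius_from_pressure(P_a, A, constants)
        assert r_back == pytest.approx(r_um * UM, rel=1e-8)

    def test_baseline_pressure_consistent_with_calibration(self, group_calib, constants):
        """The calibrated resting radius/activation balance at ≈50 mmHg."""
        P_a = pressure_from_radius(group_calib.r_base, group_calib.A_base, constants)
        assert P_a == pytest.approx(group_calib.P_a_base, rel=1e-10)
        assert P_a == pytest.approx(constants.P_a_rest, abs=0.5)

    def test_no_root_raises(self, constants):
        with pytest.raises(CalibrationError):
            radius_from_pressure(-500.0, 0.5, constants)


class TestArteriolarPowerLaws:
    def test_resistance_at_anchor(self, group_calib, constants):
        """At the anchor radius R_a = ΔP_a/Q_r = 0.4861 mmHg·min/mL."""
        R_a, _ = arteriolar_RV(group_calib.r_ref, group_calib)
        assert R_a == pytest.approx(constants.delta_P_a / constants.Q_r, rel=1e-12)
        assert R_a / 60.0 == pytest.approx(0.4861, abs=1e-4)

    def test_power_law_scaling(self, group_calib):
        r = group_calib.r_ref
        R1, V1 = arteriolar_RV(r, group_calib)
        R2, V2 = arteriolar_RV(r / 2, group_calib)
        assert R2 / R1 == pytest.approx(16.0, rel=1e-12)
        assert V2 / V1 == pytest.approx(0.25, rel=1e-12)

    def test_compliance_consistency(self, group_calib, constants):
        """C_a = V_a/ΔP_a and R_a·C_a = τ_a at the anchor."""
        R_a, V_a = arteriolar_RV(group_calib.r_ref, group_calib)
        C_a = V_a / constants.delta_P_a
        assert R_a * C_a == pytest.approx(constants.tau_a, rel=1e-12)

    def test_resistance_monotone_in_radius(self, group_calib):
        r = np.linspace(20, 300, 100) * UM
        R = np.array([arteriolar_RV(ri, group_calib)[0] for ri in r])
        assert np.all(np.diff(R) < 0)


class TestFlowsAndRhs:
    def test_baseline_flows(self, group_calib, constants):
        """Calibrated baseline delivers Q_r = 144 mL/min, f = 4.8 mL/100g/min."""
        state = CircuitState(
            group_calib.P_p_base, group_calib.r_base, group_calib.P_v_base
        )
        Q_a, Q_v, f = segment_flows(state, group_calib.A_base, group_calib, constants)
        assert Q_v * 60 == pytest.approx(144.0, rel=1e-9)
        assert Q_a == pytest.approx(Q_v, rel=1e-9)
        assert f == pytest.approx(4.8, rel=1e-9)

    def test_equal_pressures_no_flow(self, group_calib, constants):
        """With P_p = P_a = P_v there is no driving pressure anywhere."""
        A = group_calib.A_base
        r = group_calib.r_base
        P_eq = pressure_from_radius(r, A, constants)
        state = CircuitState(P_eq, r, P_eq)
        Q_a, Q_v, f = segment_flows(state, A, group_calib, constants)
        assert Q_a == pytest.approx(0.0, abs=1e-12)
        assert Q_v == pytest.approx(0.0, abs=1e-12)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_perfusion_identity(self, group_calib, constants):
        """f_ASL·V_m equals the mid-arteriole-to-vein flow by definition."""
        state = CircuitState(80.0, 70 * UM, 20.0)
        _, Q_v, f = segment_flows(state, 0.5, group_calib, constants)
        assert f * constants.V_m / 6000.0 == pytest.approx(Q_v, rel=1e-12)

    def test_baseline_rhs_is_fixed_point(self, group_calib, constants):
        state = CircuitState(
            group_calib.P_p_base, group_calib.r_base, group_calib.P_v_base
        )
        d = circuit_rhs(state, group_calib.A_base, False, group_calib, constants)
        assert np.allclose(d, 0.0, atol=1e-11)

    def test_cuff_on_arterial_pressure_decays(self, group_calib, constants):
        state = CircuitState(
            group_calib.P_p_base, group_calib.r_base, group_calib.P_v_base
        )
        d = circuit_rhs(state, group_calib.A_base, True, group_calib, constants)
        assert d[0] < 0.0

    def test_radius_rhs_matches_discrete_volume_balance(self, mean_subject):
        """Integrated arteriolar volume change equals the net inflow.

        Independent discrete-conservation oracle: over the first 20 s of
        cuffing, ΔV_a = K_V·Δ(r²) must equal ∫(Q_a − Q_v)dt evaluated by
        trapezoidal quadrature of the flows along the trajectory.
        """
        sim = simulate(mean_subject, CuffProtocol(t_cuff=60.0, t_recovery=60.0))
        calib = sim.calibration
        t = np.linspace(0.0, 20.0, 2001)
        y = sim.states(t)
        A = sim.activation_at(t)
        c = sim._constants
        net = np.empty(t.size)
        for i in range(t.size):
            st_i = CircuitState(y[i, 0], y[i, 1], y[i, 2])
            Q_a, Q_v, _ = segment_flows(st_i, float(A[i]), calib, c)
            net[i] = Q_a - Q_v
        dV_int = np.trapezoid(net, t)
        dV_state = calib.K_V * (y[-1, 1] ** 2 - y[0, 1] ** 2)
        assert dV_state == pytest.approx(dV_int, rel=1e-4)


class TestClosedSystemVolume:
    def test_total_volume_conserved_during_cuff(self, sim_5min):
        """With both switches open the circuit only redistributes volume."""
        calib = sim_5min.calibration
        t = np.linspace(0.0, 300.0, 301)
        y = sim_5min.states(t)
        total = calib.C_p * y[:, 0] + calib.K_V * y[:, 1] ** 2 + calib.C_v * y[:, 2]
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-6


class TestPressureLedger:
    def test_full_circuit_steady_state_ledger(self, group_calib, constants):
        """Baseline steady state: 1.8775 / 70 / 1 mmHg segment drops."""
        assert group_calib.P_ai - group_calib.P_p_base == pytest.approx(1.8775, abs=1e-4)
        assert group_calib.P_p_base - group_calib.P_v_base == pytest.approx(70.0, rel=1e-12)
        assert group_calib.P_v_base - constants.P_vo == pytest.approx(1.0, rel=1e-12)

    def test_full_rhs_zero_at_baseline(self, group_subject, group_calib):
        from aslrh.simulator import make_rhs

        rhs = make_rhs(group_subject, group_calib)
        d = np.array(rhs(0.0, baseline_state(group_calib)))
        assert np.max(np.abs(d)) < 1e-12
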