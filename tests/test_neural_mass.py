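"""Neural mass model: vector field, tangent system, integrators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gammaburst as gb
from gammaburst.neural_mass import MassState


def hand_rhs(y, p, theta=0.0):
    """Independent term-by-term evaluation of the mass equations."""
    RE, VE, RI, VI = y
    tE, tI = p.tau_m_E, p.tau_m_I
    return np.array([
        2 * RE * VE / tE + p.Delta_eff_E / (tE ** 2 * np.pi),
        (VE ** 2 + p.I0_E + theta) / tE - tE * (np.pi * RE) ** 2
        + p.J_EE * RE - p.J_EI * RI,
        2 * RI * VI / tI + p.Delta_eff_I / (tI ** 2 * np.pi),
        (VI ** 2 + p.I0_I) / tI - tI * (np.pi * RI) ** 2
        + p.J_IE * RE - p.J_II * RI,
    ])


class TestMassDerivatives:
    def test_decoupled_fixed_point_has_zero_derivative(self):
        p = gb.ModelParams(I0_E=-1.0, I0_I=-1.0, Delta_E=0.0, Delta_I=0.0,
                           J_EE=0, J_IE=0, J_EI=0, J_II=0)
        d = gb.mass_derivatives(MassState(0.0, -1.0, 0.0, -1.0), p)
        assert d.as_array() == pytest.approx(np.zeros(4), abs=1e-15)

    def test_rate_nullcline_closed_form(self):
        # on V = -Delta_eff / (2 pi tau R) the rate derivative vanishes
        p = gb.ModelParams(I0_E=1.0, Delta_E=0.7)
        R = 0.03
        V = -p.Delta_eff_E / (2 * np.pi * p.tau_m_E * R)
        d = gb.mass_derivatives(MassState(R, V, 0.05, -1.0), p)
        assert d.R_E == pytest.approx(0.0, abs=1e-14)

    def test_matches_independent_hand_evaluation(self):
        p = gb.ModelParams(I0_E=0.5, Delta_E=0.4)
        y = np.array([0.05, -1.0, 0.05, -1.0])
        d = gb.mass_derivatives(MassState.from_array(y), p)
        assert d.as_array() == pytest.approx(hand_rhs(y, p), rel=1e-14)

    def test_theta_drive_enters_excitatory_voltage_only(self):
        p = gb.ModelParams(I0_E=0.5, Delta_E=0.4, theta_amplitude=0.2)
        y = np.array([0.05, -1.0, 0.05, -1.0])
        t = 25.0  # sin phase = pi/2 at 10 Hz
        d = gb.mass_derivatives(MassState.from_array(y, t), p)
        assert d.as_array() == pytest.approx(hand_rhs(y, p, theta=0.2),
                                             rel=1e-12)


class TestTangentDerivatives:
    def test_zero_perturbation_maps_to_zero(self):
        p = gb.ModelParams(I0_E=0.5, Delta_E=0.4)
        base = MassState(0.05, -1.0, 0.05, -1.0)
        assert not gb.tangent_derivatives(base, np.zeros(4), p).any()

    @given(st.floats(-2, 2), st.floats(-2, 2))
    @settings(max_examples=20, deadline=None)
    def test_linearity(self, a, b):
        p = gb.ModelParams(I0_E=0.5, Delta_E=0.4)
        base = MassState(0.05, -1.0, 0.05, -1.0)
        p1 = np.array([1.0, 0.5, -0.3, 0.2])
        p2 = np.array([-0.7, 0.1, 0.9, -1.1])
        lhs = gb.tangent_derivatives(base, a * p1 + b * p2, p)
        rhs = (a * gb.tangent_derivatives(base, p1, p)
               + b * gb.tangent_derivatives(base, p2, p))
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)

    def test_matches_central_finite_differences(self):
        p = gb.ModelParams(I0_E=1.3, Delta_E=1.1)
        base = MassState(0.07, -0.8, 0.04, -0.3)
        pert = np.array([0.3, -1.0, 0.5, 0.7])
        eps = 1e-6
        ya = base.as_array()
        fd = (hand_rhs(ya + eps * pert, p) - hand_rhs(ya - eps * pert, p)) \
            / (2 * eps)
        an = gb.tangent_derivatives(base, pert, p)
        assert an == pytest.approx(fd, abs=1e-7)   # O(eps^2) truncation

    def test_jacobian_consistency_elementwise(self):
        # matrix columns from unit perturbations equal the FD Jacobian
        p = gb.ModelParams(I0_E=0.5, Delta_E=0.4)
        base = MassState(0.05, -1.0, 0.05, -1.0)
        J = gb.jacobian_at(p, base)
        eps = 1e-7
        ya = base.as_array()
        for j in range(4):
            e = np.zeros(4)
            e[j] = eps
            col = (hand_rhs(ya + e, p) - hand_rhs(ya - e, p)) / (2 * eps)
            assert J[:, j] == pytest.approx(col, rel=1e-5, abs=1e-6)


class TestIntegrateMass:
    def test_fixed_point_initialization_stays_constant(self):
        p = gb.ModelParams(I0_E=-3.0, Delta_E=3.0)
        st_, _ = gb.find_fixed_point(p)
        cfg = gb.SimulationConfig(dt=0.01, transient_s=0.0, duration_s=0.5)
        traj = gb.integrate_mass(p, cfg, initial=st_)
        assert np.abs(traj.V_E - st_.V_E).max() < 1e-9

    def test_star_point_limit_cycle_with_e_leading_i(self, star_mass):
        from gammaburst import oscillation_metrics as om
        assert om.sigma_v(star_mass.V_E) > 0.5       # sustained oscillation
        d, boundary = om.ei_delay(star_mass.R_E, star_mass.R_I,
                                  star_mass.fs_hz)
        assert not boundary
        assert d > 0                                  # E peak precedes I peak

    def test_ibg_point_shows_sensitivity_to_initial_conditions(self):
        p = gb.ModelParams(I0_E=0.5, Delta_E=0.4)
        cfg = gb.SimulationConfig(dt=0.01, transient_s=1.0, duration_s=3.0)
        a = gb.integrate_mass(p, cfg, initial=MassState(0.05, -1.0, 0.05, -1.0))
        b = gb.integrate_mass(p, cfg, initial=MassState(0.05, -1.0 + 1e-8,
                                                        0.05, -1.0))
        assert np.abs(a.V_E - b.V_E).max() > 0.1      # trajectories diverged

    def test_rk4_fourth_order_convergence(self):
        p = gb.ModelParams(I0_E=2.0, Delta_E=2.0)
        y0 = MassState(0.05, -1.0, 0.05, -1.0)

        def end_state(dt):
            cfg = gb.SimulationConfig(dt=dt, transient_s=0.0, duration_s=0.1)
            tr = gb.integrate_mass(p, cfg, initial=y0, sample_dt=dt)
            return np.array([tr.R_E[-1], tr.V_E[-1], tr.R_I[-1], tr.V_I[-1]])

        ref = end_state(0.0005)
        ratio = (np.abs(end_state(0.02) - ref).max()
                 / np.abs(end_state(0.01) - ref).max())
        assert 10 < ratio < 25                        # ~16x for order 4

    def test_divergence_reported_with_timestamp(self):
        # RK4 is unstable at this step size; the blow-up must be reported
        # with its time stamp instead of propagating NaNs
        p = gb.ModelParams(I0_E=2.0, Delta_E=2.0)
        cfg = gb.SimulationConfig(dt=0.5, transient_s=0.0, duration_s=1.0)
        with pytest.raises(FloatingPointError, match="t ="):
            gb.integrate_mass(p, cfg)


class TestFiniteSize:
    def test_huge_n_matches_deterministic(self):
        p = gb.ModelParams(I0_E=-3.0, Delta_E=3.0)
        cfg = gb.SimulationConfig(dt=0.01, transient_s=0.5, duration_s=1.0)
        det = gb.integrate_mass(p, cfg)
        fs = gb.integrate_mass_finite_size(
            p, cfg, gb.FiniteSizeConfig(10 ** 12, 10 ** 12, seed=1))
        assert np.allclose(det.V_E, fs.V_E, atol=1e-4)

    def test_sigma_v_scales_as_inverse_sqrt_n(self):
        from gammaburst import oscillation_metrics as om
        p = gb.ModelParams(I0_E=-2.5, Delta_E=2.0)   # well below the Hopf
        cfg = gb.SimulationConfig(dt=0.01, transient_s=1.0, duration_s=10.0)
        Ns = [4000, 16000, 64000]
        sv = [om.sigma_v(gb.integrate_mass_finite_size(
            p, cfg, gb.FiniteSizeConfig(N, N, seed=5)).V_E) for N in Ns]
        slope = np.polyfit(np.log(Ns), np.log(sv), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_invalid_population_size(self):
        with pytest.raises(ValueError):
            gb.FiniteSizeConfig(0, 100)


class TestDisorderEquivalence:
    def test_quenched_and_noise_enter_only_through_delta_eff(self):
        # exact at the mass level: identical trajectories
        cfg = gb.SimulationConfig(dt=0.01, transient_s=0.5, duration_s=1.0)
        a = gb.integrate_mass(gb.ModelParams(I0_E=0.5, Delta_E=0.4,
                                             Gamma_E=0.0), cfg)
        b = gb.integrate_mass(gb.ModelParams(I0_E=0.5, Delta_E=0.0,
                                             Gamma_E=0.4), cfg)
        assert np.array_equal(a.V_E, b.V_E)


class TestTrajectoryIO:
    def test_csv_roundtrip_full_precision(self, tmp_path, star_mass):
        path = tmp_path / "traj.csv"
        star_mass.to_csv(path)
        back = gb.MassTrajectory.from_csv(path)
        assert np.array_equal(back.V_E, star_mass.V_E)
        assert np.array_equal(back.R_I, star_mass.R_I)

    def test_shuffled_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t_ms,V_E,R_E,R_I,V_I\n0,1,2,3,4\n")
        with pytest.raises(ValueError, match="malformed"):
            gb.MassTrajectory.from_csv(path)
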