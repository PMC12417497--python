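"""Muscle-tendon unit: lengths, activation dynamics, contraction dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spindlearm.arm import JointState
from spindlearm.mtu import (A_MIN, C_RHO, MUSCLES, NU_H, MTUParams, MTUState,
                            activation, ce_rate_and_force, default_muscles,
                            hatze_activation_step, joint_torques, mtu_length,
                            _force_velocity, _see_force)

DEG = math.pi / 180.0
REF = JointState(psi=0.0, phi=90 * DEG)


class TestLengthModel:
    def test_reference_posture_gives_reference_length(self):
        for p in default_muscles().values():
            assert mtu_length(REF, p) == pytest.approx(p.l_ref)

    def test_elbow_flexion_shortens_elbow_flexor(self):
        p = default_muscles()["MEF"]
        q = JointState(psi=0.0, phi=80 * DEG)  # 10 deg flexion
        dl = mtu_length(q, p) - p.l_ref
        assert dl == pytest.approx(-0.03 * 10 * DEG, abs=1e-12)

    def test_biarticular_extensor_shoulder_gradient(self):
        p = default_muscles()["BEESR"]
        dpsi = 0.2
        q = JointState(psi=dpsi, phi=90 * DEG)
        dl = mtu_length(q, p) - p.l_ref
        assert dl / dpsi == pytest.approx(+0.05, abs=1e-12)


class TestActivation:
    def test_zero_stimulation_decays_to_floor(self):
        s = MTUState(l_ce=0.10, gamma_c=0.8, a=0.9)
        for _ in range(1000):
            s = hatze_activation_step(0.0, s, 0.10, 1e-3)
        assert s.a == pytest.approx(A_MIN, abs=1e-3)

    def test_full_stimulation_fixed_point(self):
        """gamma_c -> 1 with tau = 0.1 s; a(inf) from the closed form."""
        s = MTUState()
        for _ in range(100):       # 0.1 s
            s = hatze_activation_step(1.0, s, 0.10, 1e-3)
        assert s.gamma_c == pytest.approx(1 - math.exp(-1), rel=1e-6)
        for _ in range(900):       # out to 1 s
            s = hatze_activation_step(1.0, s, 0.10, 1e-3)
        a_inf = (A_MIN + C_RHO ** NU_H) / (1 + C_RHO ** NU_H)
        assert s.a == pytest.approx(a_inf, abs=1e-3)

    @given(u=st.floats(0.0, 1.0))
    def test_gamma_equilibrium_equals_stimulation(self, u):
        s = MTUState(gamma_c=u)
        s2 = hatze_activation_step(u, s, 0.10, 1e-3)
        assert s2.gamma_c == pytest.approx(u, abs=1e-12)

    @given(u=st.floats(0.0, 1.0), g0=st.floats(0.0, 1.0),
           lam=st.floats(0.5, 1.5))
    def test_activity_bounded_and_monotone_under_sustained_drive(self, u, g0, lam):
        l_ce = 0.10 * lam
        s = MTUState(l_ce=l_ce, gamma_c=g0, a=activation(g0, l_ce, 0.10))
        prev = s.gamma_c
        for _ in range(50):
            s = hatze_activation_step(u, s, l_ce, 1e-3)
            assert A_MIN <= s.a <= 1.0
            # gamma_c moves monotonically toward u
            assert (s.gamma_c - prev) * (u - prev) >= -1e-12
            prev = s.gamma_c


class TestContractionDynamics:
    def test_isometric_balance_at_max_activation(self):
        """SEE pre-tensioned to F_max, CE at optimum, a = 1: static, F = F_max."""
        p = MTUParams()
        l_ce = p.l_ce_opt
        l_mtu = l_ce + p.l_see_0 * (1 + p.eps_ref)  # F_see = F_max
        v, F = ce_rate_and_force(MTUState(l_ce=l_ce, a=1.0), l_mtu, p)
        assert v == pytest.approx(0.0, abs=1e-9)
        assert F == pytest.approx(p.F_max, rel=1e-6)

    def test_slack_floor_state_is_force_free(self):
        p = MTUParams()
        l_mtu = p.l_ce_opt + p.l_see_0  # SEE exactly slack
        v, F = ce_rate_and_force(MTUState(l_ce=p.l_ce_opt, a=A_MIN), l_mtu, p)
        assert F == 0.0
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_hill_asymptote(self):
        assert _force_velocity(-10.0, 10.0, 0.25, 1.5) == 0.0

    def test_eccentric_branch_continuous_and_saturating(self):
        p = MTUParams()
        below = _force_velocity(-1e-9, p.v_max_hat, p.curv, p.ecc_max)
        above = _force_velocity(+1e-9, p.v_max_hat, p.curv, p.ecc_max)
        assert above == pytest.approx(below, abs=1e-6)
        assert _force_velocity(50.0, p.v_max_hat, p.curv, p.ecc_max) == \
            pytest.approx(p.ecc_max, abs=1e-3)

    def test_root_matches_fine_grid_scan(self, rng):
        """Bisection root vs a grid scan of the monotone force balance.

        Oracle: evaluate the residual on a dense velocity grid, locate the
        sign change, and interpolate the crossing — independent of the
        bisection path under test.
        """
        p = MTUParams()
        vgrid = np.linspace(-4.0, 4.0, 80001)
        f_v = np.array([_force_velocity(v / p.l_ce_opt, p.v_max_hat,
                                        p.curv, p.ecc_max) for v in vgrid])
        for _ in range(1000):
            a = rng.uniform(A_MIN, 1.0)
            lam = rng.uniform(0.7, 1.3)
            l_ce = lam * p.l_ce_opt
            eps = rng.uniform(-0.01, 0.04)
            l_mtu = l_ce + p.l_see_0 * (1 + eps)
            v_mtu = rng.uniform(-0.3, 0.3)
            v, _ = ce_rate_and_force(MTUState(l_ce=l_ce, a=a), l_mtu, p, v_mtu)
            # independent residual on the grid (strictly decreasing)
            a_eff = (a - A_MIN) / (1 - A_MIN)
            F_see = _see_force(eps, p.F_max, p.eps_ref)
            f_l = math.exp(-((abs(lam - 1) / p.w_L) ** p.nu_L))
            F_pee = p.k_pee * p.F_max * max(0.0, lam - 1) ** 2
            resid = (F_see + p.d_se * (v_mtu - vgrid)
                     - p.F_max * a_eff * f_l * f_v - F_pee - p.d_pe * vgrid)
            k = int(np.searchsorted(-resid, 0.0))
            assert 0 < k < len(vgrid)
            v_scan = vgrid[k - 1] + (vgrid[k] - vgrid[k - 1]) * (
                resid[k - 1] / (resid[k - 1] - resid[k]))
            assert abs(v - v_scan) < 1e-6

    def test_isometric_mtu_settles_to_steady_state(self):
        """l_mtu held fixed: the CE creeps to a stationary length."""
        p = MTUParams()
        l_mtu = p.l_ce_opt + p.l_see_0 * 1.02
        l_ce = p.l_ce_opt
        a = 0.6
        dt = 1e-4
        for _ in range(20000):  # 2 s
            v, _ = ce_rate_and_force(MTUState(l_ce=l_ce, a=a), l_mtu, p)
            l_ce += v * dt
        v_final, _ = ce_rate_and_force(MTUState(l_ce=l_ce, a=a), l_mtu, p)
        assert abs(v_final) < 1e-6

    def test_force_nonnegative_random_states(self, rng):
        p = MTUParams()
        for _ in range(200):
            l_ce = p.l_ce_opt * rng.uniform(0.6, 1.4)
            l_mtu = l_ce + p.l_see_0 * (1 + rng.uniform(-0.05, 0.04))
            _, F = ce_rate_and_force(
                MTUState(l_ce=l_ce, a=rng.uniform(A_MIN, 1.0)), l_mtu, p,
                v_mtu=rng.uniform(-0.5, 0.5))
            assert F >= 0.0


class TestJointTorques:
    def test_zero_forces_zero_torque(self):
        assert joint_torques(np.zeros(6), default_muscles()) == (0.0, 0.0)

    def test_single_elbow_flexor(self):
        f = np.zeros(6)
        f[MUSCLES.index("MEF")] = 100.0
        ts, te = joint_torques(f, default_muscles())
        assert te == pytest.approx(+3.0)   # flexion sense
        assert ts == 0.0

    def test_antagonist_pair_cancels(self):
        f = np.zeros(6)
        f[MUSCLES.index("MEF")] = 250.0
        f[MUSCLES.index("MEE")] = 250.0
        _, te = joint_torques(f, default_muscles())
        assert te == pytest.approx(0.0)
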