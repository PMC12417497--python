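"""Hill-type muscle-tendon units with Hatze-type activation dynamics.

Each of the six arm muscles (MEF, MEE, BEFSA, BEESR, MSA, MSR) is a
contractile element (CE) with parallel elastic (PEE) and parallel damping
(PDE) elements, in series with a serial elastic (SEE) and serial damping
(SDE) element.  Muscle paths use constant signed moment arms, so the MTU
length is linear in the joint angles.

Activation dynamics follow Hatze's calcium kinetics: a first-order internal
variable ``gamma_c`` tracks the neural stimulation ``u`` with rate constant
``m_h``, and a length-dependent static nonlinearity maps it to activity
``a`` in [a_min, 1].  The active CE force is driven by the rescaled
activity (a - a_min)/(1 - a_min), so a muscle held at the activation floor
produces no active force and the slack rest state is a true equilibrium.

The CE contraction rate is the unique root of the force balance
``F_see + F_sde = F_ce(v) + F_pee + F_pde`` — the right side is strictly
increasing in ``v`` and the left side strictly decreasing, solved by
bracketed bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .arm import JointState

__all__ = [
    "MUSCLES",
    "MTUParams",
    "MTUState",
    "default_muscles",
    "mtu_length",
    "mtu_velocity",
    "hatze_activation_step",
    "activation",
    "ce_rate_and_force",
    "joint_torques",
    "pack_params",
]

MUSCLES = ("MEF", "MEE", "BEFSA", "BEESR", "MSA", "MSR")

# Hatze activation constants.  The nonlinearity gain c_rho is the
# calibration dial of the activation dynamics: it is set so that the tonic
# motoneuron firing elicited by the 380 pA descending current produces
# mid-level (~0.5) muscle activation in the closed loop.
M_H = 10.0      # 1/s, calcium kinetics rate
NU_H = 3.0      # nonlinearity exponent
C_RHO = 3.0     # length-scaled gain of the nonlinearity
A_MIN = 0.005   # activation floor

# reference posture at which muscle lengths are anchored
PSI_REF = 0.0
PHI_REF = math.pi / 2.0


@dataclass
class MTUParams:
    name: str = "MEF"
    F_max: float = 1000.0     # N
    l_ce_opt: float = 0.10    # m
    l_see_0: float = 0.15     # m, SEE slack length
    w_L: float = 0.45         # force-length width
    nu_L: float = 3.0         # force-length exponent
    v_max_hat: float = 10.0   # l_ce_opt / s
    curv: float = 0.25        # Hill curvature
    ecc_max: float = 1.5      # eccentric plateau (x F_max)
    k_pee: float = 2.0
    eps_ref: float = 0.04     # SEE reference strain
    d_se: float = 300.0       # N s / m
    d_pe: float = 50.0        # N s / m
    r_shoulder: float = 0.0   # m, signed (flexion/anteversion positive)
    r_elbow: float = 0.0      # m, signed (flexion positive)

    def __post_init__(self) -> None:
        if min(self.F_max, self.l_ce_opt, self.l_see_0, self.v_max_hat) <= 0:
            raise ValueError("F_max, l_ce_opt, l_see_0, v_max_hat must be positive")

    @property
    def l_ref(self) -> float:
        """MTU length at the reference posture.

        Chosen so that there l_ce = l_ce_opt and the SEE sits exactly at its
        slack length: the passive muscle (activity at the floor, zero active
        force) is then in equilibrium with zero transmitted force.
        """
        return self.l_ce_opt + self.l_see_0


@dataclass
class MTUState:
    l_ce: float = 0.10
    gamma_c: float = 0.0
    a: float = A_MIN

    def __post_init__(self) -> None:
        if self.l_ce <= 0:
            raise ValueError("l_ce must be positive")


def default_muscles() -> dict[str, MTUParams]:
    """The six arm muscles with uniform Hill parameters and their signed
    constant moment arms (flexion = torque increasing psi / decreasing phi)."""
    arms = {
        "MEF": (0.0, +0.03),
        "MEE": (0.0, -0.03),
        "BEFSA": (+0.05, +0.03),
        "BEESR": (-0.05, -0.03),
        "MSA": (+0.05, 0.0),
        "MSR": (-0.05, 0.0),
    }
    return {
        name: MTUParams(name=name, r_shoulder=rs, r_elbow=re)
        for name, (rs, re) in arms.items()
    }


def mtu_length(q: JointState, p: MTUParams) -> float:
    """Constant-moment-arm muscle path length.

    ``l = l_ref - r_sh (psi - psi_ref) - r_el ((pi - phi) - (pi - phi_ref))``
    so a flexor (positive moment arm) shortens during flexion.
    """
    return (p.l_ref - p.r_shoulder * (q.psi - PSI_REF)
            - p.r_elbow * ((math.pi - q.phi) - (math.pi - PHI_REF)))


def mtu_velocity(q: JointState, p: MTUParams) -> float:
    """Rate of change of the MTU length for the current joint velocities."""
    return -p.r_shoulder * q.dpsi + p.r_elbow * q.dphi


@njit(cache=True)
def _hatze_activity(gamma_c: float, lam: float) -> float:
    q = C_RHO * lam * gamma_c
    q3 = q ** NU_H
    return (A_MIN + q3) / (1.0 + q3)


@njit(cache=True)
def _hatze_gamma_step(gamma_c: float, u: float, dt: float) -> float:
    # exact update of gamma_c' = m_h (u - gamma_c)
    return gamma_c + (u - gamma_c) * (1.0 - math.exp(-M_H * dt))


def activation(gamma_c: float, l_ce: float, l_ce_opt: float) -> float:
    """Static Hatze nonlinearity: activity from free-calcium and CE length."""
    return float(_hatze_activity(gamma_c, l_ce / l_ce_opt))


def hatze_activation_step(u: float, s: MTUState, l_ce: float, dt: float,
                          p: MTUParams | None = None) -> MTUState:
    """Advance the activation dynamics one step of ``dt`` seconds.

    ``gamma_c`` relaxes exponentially toward the stimulation ``u`` (time
    constant 1/m_h = 0.1 s); the activity ``a`` follows algebraically.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0.0 <= u <= 1.0:
        raise ValueError("stimulation must lie in [0, 1]")
    l_opt = p.l_ce_opt if p is not None else 0.10
    g = _hatze_gamma_step(s.gamma_c, u, dt)
    return MTUState(l_ce=l_ce, gamma_c=g, a=activation(g, l_ce, l_opt))


# --- packed-parameter layout shared with the compiled episode kernel -------
# rows of the (15, 6) parameter matrix
P_FMAX, P_LOPT, P_LSEE, P_WL, P_NUL, P_VMAX, P_CURV, P_ECC, P_KPEE, \
    P_EPSR, P_DSE, P_DPE, P_RSH, P_REL, P_LREF = range(15)


def pack_params(muscles: dict[str, MTUParams]) -> np.ndarray:
    """Pack per-muscle parameters into the (6, 15) matrix kernels consume
    (one contiguous row per muscle, columns indexed by the P_* constants)."""
    P = np.empty((len(MUSCLES), 15))
    for j, name in enumerate(MUSCLES):
        P[j] = _single_col(muscles[name])
    return P


@njit(cache=True)
def _force_length(lam: float, w_L: float, nu_L: float) -> float:
    return math.exp(-((abs(lam - 1.0) / w_L) ** nu_L))


@njit(cache=True)
def _force_velocity(vhat: float, v_max: float, curv: float, ecc: float) -> float:
    if vhat <= -v_max:
        return 0.0
    if vhat <= 0.0:
        return (1.0 + vhat / v_max) / (1.0 - vhat / (v_max * curv))
    # eccentric branch: saturates at ecc, slope-matched to the hyperbola at 0
    k0 = (1.0 + 1.0 / curv) / v_max
    return ecc - (ecc - 1.0) * math.exp(-k0 * vhat / (ecc - 1.0))


@njit(cache=True)
def _see_force(eps: float, F_max: float, eps_ref: float) -> float:
    if eps <= 0.0:
        return 0.0
    if eps <= 2.0 * eps_ref:
        return F_max * (eps / eps_ref) ** 2
    # linear continuation, slope-matched at eps = 2 eps_ref
    return 4.0 * F_max + (4.0 * F_max / eps_ref) * (eps - 2.0 * eps_ref)


@njit(cache=True)
def _balance(v: float, a: float, l_ce: float, l_mtu: float, v_mtu: float,
             pc: np.ndarray) -> float:
    """Residual of the CE force balance; strictly decreasing in v."""
    a_eff = max(0.0, (a - A_MIN) / (1.0 - A_MIN))
    lam = l_ce / pc[P_LOPT]
    eps = (l_mtu - l_ce - pc[P_LSEE]) / pc[P_LSEE]
    F_see = _see_force(eps, pc[P_FMAX], pc[P_EPSR])
    f_l = _force_length(lam, pc[P_WL], pc[P_NUL])
    f_v = _force_velocity(v / pc[P_LOPT], pc[P_VMAX], pc[P_CURV], pc[P_ECC])
    F_ce = pc[P_FMAX] * a_eff * f_l * f_v
    F_pee = pc[P_KPEE] * pc[P_FMAX] * max(0.0, lam - 1.0) ** 2
    return F_see + pc[P_DSE] * (v_mtu - v) - F_ce - F_pee - pc[P_DPE] * v


@njit(cache=True)
def _ce_rate_force(a: float, l_ce: float, l_mtu: float, v_mtu: float,
                   pc: np.ndarray) -> tuple[float, float]:
    """CE contraction rate and transmitted MTU force for one muscle.

    Root of the force balance by bracketed bisection to 1e-10 N; the bracket
    is widened once if the residual does not change sign inside it.  Terms
    that do not depend on the contraction rate are hoisted out of the loop,
    so the residual g(v) = const - (d_se + d_pe) v - F_act f_V(v / l_opt).
    """
    a_eff = max(0.0, (a - A_MIN) / (1.0 - A_MIN))
    l_opt = pc[P_LOPT]
    lam = l_ce / l_opt
    eps = (l_mtu - l_ce - pc[P_LSEE]) / pc[P_LSEE]
    F_see = _see_force(eps, pc[P_FMAX], pc[P_EPSR])
    F_act = pc[P_FMAX] * a_eff * _force_length(lam, pc[P_WL], pc[P_NUL])
    F_pee = pc[P_KPEE] * pc[P_FMAX] * max(0.0, lam - 1.0) ** 2
    const = F_see + pc[P_DSE] * v_mtu - F_pee
    d_tot = pc[P_DSE] + pc[P_DPE]
    v_max, curv, ecc = pc[P_VMAX], pc[P_CURV], pc[P_ECC]

    span = 2.0 * v_max * l_opt
    lo, hi = -span, span
    for _ in range(2):
        glo = const - d_tot * lo - F_act * _force_velocity(lo / l_opt, v_max, curv, ecc)
        ghi = const - d_tot * hi - F_act * _force_velocity(hi / l_opt, v_max, curv, ecc)
        if glo * ghi <= 0.0:
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise FloatingPointError("CE force balance has no root in bracket")
    v = 0.0
    for _ in range(80):
        v = 0.5 * (lo + hi)
        g = const - d_tot * v - F_act * _force_velocity(v / l_opt, v_max, curv, ecc)
        if abs(g) < 1e-10:
            break
        if g > 0.0:
            lo = v
        else:
            hi = v
    F_mtu = F_see + pc[P_DSE] * (v_mtu - v)
    return v, max(0.0, F_mtu)


def ce_rate_and_force(s: MTUState, l_mtu: float, p: MTUParams,
                      v_mtu: float = 0.0) -> tuple[float, float]:
    """Contraction rate dl_ce/dt (m/s) and transmitted force F_mtu (N).

    ``v_mtu`` is the current rate of change of the whole-muscle path length,
    needed by the serial damping element.  The transmitted force is clamped
    at zero: a tendon cannot push.
    """
    if l_mtu <= s.l_ce:
        raise ValueError("l_mtu must exceed l_ce (positive SEE length)")
    pc = _single_col(p)
    v, F = _ce_rate_force(s.a, s.l_ce, l_mtu, v_mtu, pc)
    return float(v), float(F)


def _single_col(p: MTUParams) -> np.ndarray:
    return np.array([p.F_max, p.l_ce_opt, p.l_see_0, p.w_L, p.nu_L,
                     p.v_max_hat, p.curv, p.ecc_max, p.k_pee, p.eps_ref,
                     p.d_se, p.d_pe, p.r_shoulder, p.r_elbow, p.l_ref])


def joint_torques(forces: np.ndarray, muscles: dict[str, MTUParams]) -> tuple[float, float]:
    """Sum muscle forces into joint torques (flexion-positive convention).

    Returns ``(tau_shoulder, tau_elbow)`` where positive shoulder torque
    drives anteversion (increasing psi) and positive elbow torque drives
    flexion (decreasing phi).
    """
    tau_s = 0.0
    tau_e = 0.0
    for j, name in enumerate(MUSCLES):
        p = muscles[name]
        tau_s += p.r_shoulder * float(forces[j])
        tau_e += p.r_elbow * float(forces[j])
    return tau_s, tau_e


def generalized_torques(forces: np.ndarray, muscles: dict[str, MTUParams]) -> np.ndarray:
    """Torques conjugate to (psi, phi): elbow flexion decreases phi, so the
    generalised elbow torque is the negated flexion torque."""
    ts, te = joint_torques(forces, muscles)
    return np.array([ts, -te])
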