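"""Rigid-body dynamics of the planar two-link arm in the vertical XZ-plane.

The arm hangs from a fixed shoulder at the origin and moves under gravity.
Angle conventions:

* ``psi`` — shoulder angle, measured from the downward vertical; positive
  rotation carries the hand toward +X (anteversion).
* ``phi`` — interior elbow angle between upper arm and forearm; ``pi`` is a
  fully extended arm, 90 deg puts the forearm at a right angle to the upper
  arm.

With segment lengths L1 = L2 = 0.33 m the reference posture
(psi, phi) = (0 deg, 90 deg) places the hand at (0.33, -0.33) m, the start
position of the center-out reaching task.

Segments are modelled as uniform rods (centre of mass at mid-segment,
inertia m L^2/12 about the COM).  A perturbation mass ``m_add`` is applied
as a point mass at the forearm COM.  Soft joint-limit stops (spring-damper
penalty torques) keep the elbow inside [10 deg, 175 deg] and the shoulder
inside [-60 deg, 120 deg] during early, badly-coordinated optimisation
candidates; set ``limit_stiffness = 0`` to disable them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from numba import njit

__all__ = [
    "ArmParams",
    "JointState",
    "CartesianPoint",
    "forward_kinematics",
    "gravity_torque",
    "mass_matrix",
    "joint_accelerations",
    "step_dynamics",
    "total_energy",
    "trajectory_frame",
]

_DEG = math.pi / 180.0


class CartesianPoint(NamedTuple):
    """Point in the vertical plane: x horizontal, z vertical (positive up)."""

    x: float
    z: float


@dataclass
class JointState:
    psi: float = 0.0
    phi: float = 90.0 * _DEG
    dpsi: float = 0.0
    dphi: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.psi, self.phi, self.dpsi, self.dphi])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "JointState":
        return cls(*(float(v) for v in y[:4]))


@dataclass
class ArmParams:
    """Geometry, inertia and joint-level dissipation of the two-link arm."""

    L1: float = 0.33
    L2: float = 0.33
    m1: float = 2.10
    m2: float = 1.65
    m_add: float = 0.0
    g: float = 9.81
    b_joint: float = 0.1
    com1_frac: float = 0.5
    com2_frac: float = 0.5
    shoulder_limits: tuple[float, float] = (-60.0 * _DEG, 120.0 * _DEG)
    elbow_limits: tuple[float, float] = (10.0 * _DEG, 175.0 * _DEG)
    limit_stiffness: float = 50.0
    limit_damping: float = 1.0

    def __post_init__(self) -> None:
        if min(self.L1, self.L2, self.m1, self.m2) <= 0:
            raise ValueError("segment lengths and masses must be positive")
        if self.m_add < 0 or self.g <= 0 or self.b_joint < 0:
            raise ValueError("m_add >= 0, g > 0, b_joint >= 0 required")

    def packed(self) -> np.ndarray:
        """Flat parameter vector consumed by the compiled dynamics kernel."""
        m2t = self.m2 + self.m_add
        a1 = self.com1_frac * self.L1
        a2 = self.com2_frac * self.L2
        I1 = self.m1 * self.L1 ** 2 / 12.0
        I2 = self.m2 * self.L2 ** 2 / 12.0  # point mass adds no own inertia
        return np.array([
            self.L1, self.L2, self.m1, m2t, self.g, self.b_joint,
            a1, a2, I1, I2,
            self.shoulder_limits[0], self.shoulder_limits[1],
            self.elbow_limits[0], self.elbow_limits[1],
            self.limit_stiffness, self.limit_damping,
        ])


def forward_kinematics(q: JointState, p: ArmParams) -> tuple[CartesianPoint, CartesianPoint]:
    """Elbow and hand position for a given posture.

    The absolute forearm angle (from the downward vertical) is
    ``beta = psi + (pi - phi)``.
    """
    ex = p.L1 * math.sin(q.psi)
    ez = -p.L1 * math.cos(q.psi)
    beta = q.psi + (math.pi - q.phi)
    hx = ex + p.L2 * math.sin(beta)
    hz = ez - p.L2 * math.cos(beta)
    return CartesianPoint(ex, ez), CartesianPoint(hx, hz)


def mass_matrix(q: JointState, p: ArmParams) -> np.ndarray:
    """Generalised mass matrix in (psi, phi) coordinates."""
    A = p.packed()
    Mth = _theta_mass(q.psi, q.psi + math.pi - q.phi, A)
    # theta = T q + const with T = [[1, 0], [1, -1]]; M_q = T^T M_theta T
    T = np.array([[1.0, 0.0], [1.0, -1.0]])
    return T.T @ Mth @ T


def gravity_torque(q: JointState, p: ArmParams) -> np.ndarray:
    """Generalised gravity torque G(q) conjugate to (psi, phi).

    ``joint_accelerations(q, tau=G(q))`` with zero velocities yields zero
    accelerations (static equilibrium).
    """
    A = p.packed()
    th1 = q.psi
    th2 = q.psi + math.pi - q.phi
    g1 = (A[2] * A[6] + A[3] * A[0]) * A[4] * math.sin(th1)
    g2 = A[3] * A[7] * A[4] * math.sin(th2)
    # Q_theta = T^{-T} Q_q  =>  Q_q = T^T Q_theta
    return np.array([g1 + g2, -g2])


@njit(cache=True)
def _theta_mass(th1: float, th2: float, A: np.ndarray) -> np.ndarray:
    m1, m2t = A[2], A[3]
    L1, a1, a2, I1, I2 = A[0], A[6], A[7], A[8], A[9]
    c12 = math.cos(th1 - th2)
    M = np.empty((2, 2))
    M[0, 0] = m1 * a1 * a1 + I1 + m2t * L1 * L1
    M[0, 1] = m2t * L1 * a2 * c12
    M[1, 0] = M[0, 1]
    M[1, 1] = m2t * a2 * a2 + I2
    return M


@njit(cache=True)
def _limit_torque(x: float, dx: float, lo: float, hi: float, k: float, c: float) -> float:
    if k <= 0.0:  # stops disabled entirely (spring and damper)
        return 0.0
    if x < lo:
        return -k * (x - lo) - c * dx
    if x > hi:
        return -k * (x - hi) - c * dx
    return 0.0


@njit(cache=True)
def _accel(psi: float, phi: float, dpsi: float, dphi: float,
           tau_psi: float, tau_phi: float, A: np.ndarray) -> tuple[float, float]:
    """Joint accelerations (psi'', phi'') given applied generalised torques.

    Gravity, viscous joint damping and joint-limit penalty torques are added
    internally; ``tau`` is the externally applied (e.g. muscular) torque pair
    conjugate to (psi, phi).
    """
    L1, g = A[0], A[4]
    m1, m2t, b = A[2], A[3], A[5]
    a1, a2, I1, I2 = A[6], A[7], A[8], A[9]

    th1 = psi
    th2 = psi + math.pi - phi
    dth1 = dpsi
    dth2 = dpsi - dphi

    c12 = math.cos(th1 - th2)
    s12 = math.sin(th1 - th2)

    M11 = m1 * a1 * a1 + I1 + m2t * L1 * L1
    M12 = m2t * L1 * a2 * c12
    M22 = m2t * a2 * a2 + I2

    c1 = m2t * L1 * a2 * s12 * dth2 * dth2
    c2 = -m2t * L1 * a2 * s12 * dth1 * dth1
    g1 = (m1 * a1 + m2t * L1) * g * math.sin(th1)
    g2 = m2t * a2 * g * math.sin(th2)

    tp = tau_psi - b * dpsi + _limit_torque(psi, dpsi, A[10], A[11], A[14], A[15])
    tf = tau_phi - b * dphi + _limit_torque(phi, dphi, A[12], A[13], A[14], A[15])

    # Q_theta = T^{-T} Q_q with T = [[1,0],[1,-1]] (T^{-1} = T)
    Q1 = tp + tf
    Q2 = -tf

    r1 = Q1 - c1 - g1
    r2 = Q2 - c2 - g2
    det = M11 * M22 - M12 * M12
    ddth1 = (M22 * r1 - M12 * r2) / det
    ddth2 = (M11 * r2 - M12 * r1) / det
    return ddth1, ddth1 - ddth2


def joint_accelerations(q: JointState, tau: np.ndarray, p: ArmParams) -> np.ndarray:
    """Solve M(q) q'' + C(q, q') q' + G(q) + b q' = tau for q''.

    ``tau`` is the applied (muscular) generalised torque pair conjugate to
    (psi, phi); joint-limit penalty torques are included when the posture
    is outside the stops.
    """
    A = p.packed()
    M = mass_matrix(q, p)
    if np.linalg.det(M) <= 0:  # cannot occur for positive masses/lengths
        raise AssertionError("singular mass matrix")
    dd = _accel(q.psi, q.phi, q.dpsi, q.dphi, float(tau[0]), float(tau[1]), A)
    return np.array(dd)


@njit(cache=True)
def _rk4_arm(y: np.ndarray, taus: np.ndarray, h: float, n_steps: int,
             sample_every: int, A: np.ndarray, out: np.ndarray) -> None:
    """Fixed-step RK4 on the bare arm.  ``taus`` holds torques on the
    half-step grid (2*n_steps + 1 rows) so all RK4 stages see consistent
    inputs; samples every ``sample_every`` steps land in ``out``."""
    s = 0
    for k in range(n_steps):
        r = 2 * k
        dd = _accel(y[0], y[1], y[2], y[3], taus[r, 0], taus[r, 1], A)
        k1 = np.array([y[2], y[3], dd[0], dd[1]])
        yy = y + 0.5 * h * k1
        dd = _accel(yy[0], yy[1], yy[2], yy[3], taus[r + 1, 0], taus[r + 1, 1], A)
        k2 = np.array([yy[2], yy[3], dd[0], dd[1]])
        yy = y + 0.5 * h * k2
        dd = _accel(yy[0], yy[1], yy[2], yy[3], taus[r + 1, 0], taus[r + 1, 1], A)
        k3 = np.array([yy[2], yy[3], dd[0], dd[1]])
        yy = y + h * k3
        dd = _accel(yy[0], yy[1], yy[2], yy[3], taus[r + 2, 0], taus[r + 2, 1], A)
        k4 = np.array([yy[2], yy[3], dd[0], dd[1]])
        y += (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (k + 1) % sample_every == 0:
            s += 1
            out[s] = y


def step_dynamics(q: JointState, tau_fn: Callable[[float], np.ndarray],
                  dt_window: float, p: ArmParams, *, t0: float = 0.0,
                  h: float = 1e-4, sample_dt: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the arm over ``dt_window`` seconds with applied torques.

    Returns ``(t, Y)`` where ``t`` is the 1 ms sample grid (the retained
    initial sample plus ``dt_window / sample_dt`` new ones) and ``Y`` the
    corresponding (psi, phi, dpsi, dphi) rows.  Internally a fixed-step
    4th-order Runge-Kutta scheme at step ``h`` is used; successive calls
    starting from the returned final state are continuous.
    """
    if dt_window <= 0:
        raise ValueError("dt_window must be positive")
    n_steps = int(round(dt_window / h))
    sample_every = int(round(sample_dt / h))
    A = p.packed()
    taus = np.empty((2 * n_steps + 1, 2))
    for i in range(2 * n_steps + 1):
        taus[i] = np.asarray(tau_fn(t0 + 0.5 * h * i), dtype=float)
    n_samples = n_steps // sample_every
    out = np.empty((n_samples + 1, 4))
    y = q.as_array()
    out[0] = y
    _rk4_arm(y, taus, h, n_steps, sample_every, A, out)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite arm state during integration")
    t = t0 + sample_dt * np.arange(n_samples + 1)
    return t, out


def total_energy(q: JointState, p: ArmParams) -> float:
    """Kinetic plus gravitational potential energy of the arm."""
    A = p.packed()
    th1 = q.psi
    th2 = q.psi + math.pi - q.phi
    dth = np.array([q.dpsi, q.dpsi - q.dphi])
    M = _theta_mass(th1, th2, A)
    ke = 0.5 * dth @ M @ dth
    m1, m2t, g = A[2], A[3], A[4]
    a1, a2, L1 = A[6], A[7], A[0]
    pe = -(m1 * a1 + m2t * L1) * g * math.cos(th1) - m2t * a2 * g * math.cos(th2)
    return float(ke + pe)


def trajectory_frame(t: np.ndarray, Y: np.ndarray, p: ArmParams):
    """Trajectory as a pandas DataFrame (t_s, joint angles, hand position)."""
    import pandas as pd

    hands = np.empty((len(t), 2))
    for i in range(len(t)):
        _, hand = forward_kinematics(JointState.from_array(Y[i]), p)
        hands[i] = hand
    return pd.DataFrame({
        "t_s": t, "psi_rad": Y[:, 0], "phi_rad": Y[:, 1],
        "dpsi": Y[:, 2], "dphi": Y[:, 3],
        "hand_x_m": hands[:, 0], "hand_z_m": hands[:, 1],
    })
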