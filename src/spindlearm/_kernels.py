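"""Numba-compiled inner loops of the closed-loop simulation.

Two kernels carry the whole per-window workload:

* ``lif_window_kernel`` — clock-driven update of the spiking circuit for
  one exchange window (affine subthreshold propagator, ring-buffered 1 ms
  synaptic delays, Bernoulli-thinned Poisson encoders).
* ``mech_window_kernel`` — fixed-step RK4 integration of the mechanical
  plant (arm + 6 MTUs + 6 spindles) for one window, with stimulation
  traces supplied on the half-step grid so every RK4 stage sees a
  consistent input, and logs sampled on the 1 ms grid.

The scalar muscle/spindle/arm primitives live in their own modules and are
shared with the pure-Python operation wrappers, so there is a single
numeric code path.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .arm import _accel
from .mtu import (M_H, PHI_REF, PSI_REF, P_LOPT, P_LREF, P_REL, P_RSH,
                  _ce_rate_force, _hatze_activity)
from .spindle import _spindle_rates

# state vector layout for the mechanical plant (34 entries)
_IL = 4    # l_ce[6]
_IGM = 10  # muscle gamma_c[6]
_IB1 = 16  # spindle bag1 gamma_c[6]
_IB2 = 22  # spindle bag2 gamma_c[6]
_ICH = 28  # spindle chain gamma_c[6]
N_STATE = 34


@njit(cache=True)
def lif_window_kernel(P, x, refrac, buf_e, buf_i, ptr,
                      conn_start, conn_post, conn_winc,
                      p_enc, unif, n_steps, delay_steps,
                      V_th, V_reset, tref_steps, n_neurons,
                      out_unit, out_step):
    """Advance all neurons ``n_steps`` steps; returns (n_spikes, ptr).

    ``P`` is the 6x6 affine propagator for (y1e, y2e, y1i, y2i, V, 1);
    ``conn_*`` is the CSR adjacency by presynaptic unit with the alpha-
    current increment folded into the weight; ``p_enc`` the per-step spike
    probability of each Poisson encoder and ``unif`` its uniform draws.
    """
    D = delay_steps + 1
    n = x.shape[1]
    n_enc = p_enc.shape[0]
    nsp = 0
    for k in range(n_steps):
        slot = ptr
        dest = (ptr + delay_steps) % D
        for i in range(n):
            x[0, i] += buf_e[slot, i]
            x[2, i] += buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0
        for i in range(n):
            y1e = x[0, i]
            y2e = x[1, i]
            y1i = x[2, i]
            y2i = x[3, i]
            V = x[4, i]
            Vn = (P[4, 0] * y1e + P[4, 1] * y2e + P[4, 2] * y1i
                  + P[4, 3] * y2i + P[4, 4] * V + P[4, 5])
            x[0, i] = P[0, 0] * y1e
            x[1, i] = P[1, 0] * y1e + P[1, 1] * y2e
            x[2, i] = P[2, 2] * y1i
            x[3, i] = P[3, 2] * y1i + P[3, 3] * y2i
            if refrac[i] > 0:
                refrac[i] -= 1
                x[4, i] = V_reset
            elif Vn >= V_th:
                out_unit[nsp] = i
                out_step[nsp] = k
                nsp += 1
                x[4, i] = V_reset
                refrac[i] = tref_steps
                for cix in range(conn_start[i], conn_start[i + 1]):
                    w = conn_winc[cix]
                    if w >= 0.0:
                        buf_e[dest, conn_post[cix]] += w
                    else:
                        buf_i[dest, conn_post[cix]] += w
            else:
                x[4, i] = Vn
        for e in range(n_enc):
            if unif[k, e] < p_enc[e]:
                u = n_neurons + e
                out_unit[nsp] = u
                out_step[nsp] = k
                nsp += 1
                for cix in range(conn_start[u], conn_start[u + 1]):
                    w = conn_winc[cix]
                    if w >= 0.0:
                        buf_e[dest, conn_post[cix]] += w
                    else:
                        buf_i[dest, conn_post[cix]] += w
        ptr = (ptr + 1) % D
    return nsp, ptr


@njit(cache=True)
def _mech_deriv(y, ua, ugd, ugs, A, Pm, sp, dy, aux):
    """Time derivative of the mechanical state plus logged auxiliaries.

    ``aux`` rows: 0 activity a, 1 transmitted force F, 2 CE length, 3 Ia
    rate, 4 II rate (one column per muscle).
    """
    psi = y[0]
    phi = y[1]
    dpsi = y[2]
    dphi = y[3]
    tau_s = 0.0
    tau_e = 0.0
    gc3 = np.empty(3)
    for m in range(6):
        pc = Pm[m]
        l_mtu = (pc[P_LREF] - pc[P_RSH] * (psi - PSI_REF)
                 - pc[P_REL] * ((math.pi - phi) - (math.pi - PHI_REF)))
        v_mtu = -pc[P_RSH] * dpsi + pc[P_REL] * dphi
        l_ce = y[_IL + m]
        lam = l_ce / pc[P_LOPT]
        a = _hatze_activity(y[_IGM + m], lam)
        v, F = _ce_rate_force(a, l_ce, l_mtu, v_mtu, pc)
        tau_s += pc[P_RSH] * F
        tau_e += pc[P_REL] * F
        dy[_IL + m] = v
        dy[_IGM + m] = M_H * (ua[m] - y[_IGM + m])
        dy[_IB1 + m] = M_H * (ugd[m] - y[_IB1 + m])
        dy[_IB2 + m] = M_H * (ugs[m] - y[_IB2 + m])
        dy[_ICH + m] = M_H * (ugs[m] - y[_ICH + m])
        gc3[0] = y[_IB1 + m]
        gc3[1] = y[_IB2 + m]
        gc3[2] = y[_ICH + m]
        ia, ii = _spindle_rates(lam, v / pc[P_LOPT], gc3, sp)
        aux[0, m] = a
        aux[1, m] = F
        aux[2, m] = l_ce
        aux[3, m] = ia
        aux[4, m] = ii
    # elbow flexion decreases phi: generalized elbow torque is -tau_e
    ddpsi, ddphi = _accel(psi, phi, dpsi, dphi, tau_s, -tau_e, A)
    dy[0] = dpsi
    dy[1] = dphi
    dy[2] = ddpsi
    dy[3] = ddphi


@njit(cache=True)
def mech_window_kernel(y, uh_a, uh_gd, uh_gs, A, Pm, sp, h, n_steps,
                       sample_every, out_states, out_aux, s0):
    """Integrate the plant over one window with RK4 at step ``h``.

    ``uh_*`` hold the 18 stimulation traces on the half-step grid
    (2 n_steps + 1 rows, 6 columns).  Samples land in ``out_states``
    (rows s0+1 ...; columns psi, phi, dpsi, dphi) and ``out_aux`` (rows as
    states; 30 columns = a, F, l_ce, Ia, II per muscle).  Returns the
    number of samples written.
    """
    dy = np.empty(N_STATE)
    aux = np.empty((5, 6))
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    yy = np.empty(N_STATE)
    s = 0
    for k in range(n_steps):
        r = 2 * k
        _mech_deriv(y, uh_a[r], uh_gd[r], uh_gs[r], A, Pm, sp, dy, aux)
        k1[:] = dy
        for i in range(N_STATE):
            yy[i] = y[i] + 0.5 * h * k1[i]
        _mech_deriv(yy, uh_a[r + 1], uh_gd[r + 1], uh_gs[r + 1], A, Pm, sp, dy, aux)
        k2[:] = dy
        for i in range(N_STATE):
            yy[i] = y[i] + 0.5 * h * k2[i]
        _mech_deriv(yy, uh_a[r + 1], uh_gd[r + 1], uh_gs[r + 1], A, Pm, sp, dy, aux)
        k3[:] = dy
        for i in range(N_STATE):
            yy[i] = y[i] + h * k3[i]
        _mech_deriv(yy, uh_a[r + 2], uh_gd[r + 2], uh_gs[r + 2], A, Pm, sp, dy, aux)
        k4[:] = dy
        for i in range(N_STATE):
            y[i] += (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if (k + 1) % sample_every == 0:
            s += 1
            _mech_deriv(y, uh_a[r + 2], uh_gd[r + 2], uh_gs[r + 2], A, Pm, sp, dy, aux)
            for i in range(4):
                out_states[s0 + s, i] = y[i]
            for m in range(6):
                for j in range(5):
                    out_aux[s0 + s, 5 * m + j] = aux[j, m]
    return s


@njit(cache=True)
def sample_aux(y, ua, ugd, ugs, A, Pm, sp):
    """Auxiliary log row (a, F, l_ce, Ia, II per muscle) for a state."""
    dy = np.empty(N_STATE)
    aux = np.empty((5, 6))
    _mech_deriv(y, ua, ugd, ugs, A, Pm, sp, dy, aux)
    out = np.empty(30)
    for m in range(6):
        for j in range(5):
            out[5 * m + j] = aux[j, m]
    return out
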