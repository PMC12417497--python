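"""Intrafusal muscle-spindle model: bag1, bag2 and chain fibers.

The three intrafusal fibers lie in parallel with the muscle belly, so their
length is slaved to the normalized extrafusal CE length ``lambda`` — a
quasi-static sensory-stretch mapping rather than an independent intrafusal
mechanical ODE.  Each fiber has a polar (contractile) region activated by
fusimotor drive through the same Hatze kinetics as the extrafusal fibers:
dynamic gamma stimulation drives bag1 only, static gamma drives bag2 and
chain.  Polar contraction pre-stretches the sensory region, biasing the
afferent output.

The primary (Ia) ending combines the dynamic branch (bag1) with the static
branch (bag2 + chain) through partial occlusion: the larger branch signal
dominates and the smaller contributes only a fraction ``S_occ``.  Bag1
velocity sensitivity is boosted by its own polar activation (``c_dyn``).
The secondary (II) ending reads the static fibers only, so it codes length
but not velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit

from .mtu import _hatze_activity, _hatze_gamma_step

__all__ = [
    "FIBERS",
    "SpindleParams",
    "SpindleState",
    "AfferentRates",
    "spindle_step",
    "gamma_routing",
    "pack_spindle",
]

FIBERS = ("bag1", "bag2", "chain")


class AfferentRates(NamedTuple):
    Ia: float
    II: float


@dataclass
class SpindleParams:
    # per fiber (bag1, bag2, chain)
    K_L: tuple[float, float, float] = (50.0, 150.0, 150.0)    # pps per unit stretch
    K_V: tuple[float, float, float] = (120.0, 20.0, 20.0)     # pps per (l_opt/s)
    beta_a: tuple[float, float, float] = (0.10, 0.10, 0.10)   # stretch per activation
    lambda_rest: float = 0.95   # normalized length with zero sensory stretch
    c_dyn: float = 2.0          # dynamic-gain boost per unit bag1 activation
    S_occ: float = 0.156        # partial-occlusion factor
    r_cap: float = 300.0        # pps, afferent rate ceiling

    def __post_init__(self) -> None:
        if min(*self.K_L, *self.K_V, *self.beta_a) < 0:
            raise ValueError("spindle gains must be non-negative")
        if not 0.0 <= self.S_occ <= 1.0 or self.r_cap <= 0:
            raise ValueError("0 <= S_occ <= 1 and r_cap > 0 required")


@dataclass
class SpindleState:
    gamma_c: np.ndarray = field(default_factory=lambda: np.zeros(3))
    a: np.ndarray = field(default_factory=lambda: np.full(3, 0.005))


def pack_spindle(p: SpindleParams) -> np.ndarray:
    """Flat parameter vector for the compiled episode kernel."""
    return np.array([*p.K_L, *p.K_V, *p.beta_a,
                     p.lambda_rest, p.c_dyn, p.S_occ, p.r_cap])


@njit(cache=True)
def _spindle_rates(lam: float, dlam: float, gc: np.ndarray,
                   sp: np.ndarray) -> tuple[float, float]:
    """Ia and II rates from the fiber polar activations and muscle length.

    Polar activation enters above the activation floor (same convention as
    the extrafusal active force), so zero fusimotor drive contributes no
    sensory stretch and the unbiased spindle is silent at the rest length.
    """
    r_cap = sp[12]
    a_b1 = (_hatze_activity(gc[0], lam) - 0.005) / 0.995
    P = np.empty(3)
    s = np.empty(3)
    for f in range(3):
        a_f = (_hatze_activity(gc[f], lam) - 0.005) / 0.995
        s[f] = max(0.0, (lam - sp[9]) + sp[6 + f] * a_f)
        boost = 1.0 + sp[10] * a_b1 if f == 0 else 1.0
        P[f] = min(max(sp[f] * s[f] + sp[3 + f] * boost * max(0.0, dlam), 0.0), r_cap)
    stat = P[1] + P[2]
    ia = max(P[0], stat) + sp[11] * min(P[0], stat)
    ii = 0.5 * sp[1] * s[1] + sp[2] * s[2]
    return min(max(ia, 0.0), r_cap), min(max(ii, 0.0), r_cap)


def spindle_step(lam: float, dlam: float, u_gd: float, u_gs: float,
                 s: SpindleState, p: SpindleParams, dt: float
                 ) -> tuple[SpindleState, AfferentRates]:
    """Advance the polar activations one step and emit afferent rates.

    ``lam`` is the normalized CE length, ``dlam`` its rate (1/s); ``u_gd``
    and ``u_gs`` are the dynamic/static fusimotor stimulations in [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if lam <= 0:
        raise ValueError("normalized length must be positive")
    sp = pack_spindle(p)
    gc = s.gamma_c.copy()
    drives = (u_gd, u_gs, u_gs)  # bag1 <- gamma_d; bag2, chain <- gamma_s
    for f in range(3):
        gc[f] = _hatze_gamma_step(gc[f], drives[f], dt)
    a = np.array([_hatze_activity(gc[f], lam) for f in range(3)])
    ia, ii = _spindle_rates(lam, dlam, gc, sp)
    return SpindleState(gamma_c=gc, a=a), AfferentRates(float(ia), float(ii))


def gamma_routing(spikes_gd: np.ndarray, spikes_gs: np.ndarray,
                  window: float, dt: float = 1e-3
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Convert gamma spike trains to fusimotor stimulation traces.

    Applies the spike-to-stimulation conversion (reset to one, exponential
    decay with tau = 0.01 s) independently to the dynamic and static
    streams, sampled on the ``dt`` grid over ``[0, window]``.
    """
    from .cosim import spike_to_stimulation

    grid = np.arange(0.0, window + 0.5 * dt, dt)
    return spike_to_stimulation(spikes_gd, grid), spike_to_stimulation(spikes_gs, grid)
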