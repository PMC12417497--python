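"""Spiking spinal circuit: neuron pools, connectivity, window simulation.

Six neuron pools per muscle — alpha, dynamic gamma (gd) and static gamma
(gs) motoneurons, Ia inhibitory (IaIN), propriospinal (PN) and Renshaw (R)
interneurons — each represented by a single leaky integrate-and-fire neuron
with alpha-shaped synaptic currents (separate excitatory and inhibitory
ports) and a constant descending current ``I_e`` standing in for supraspinal
drive.  Spindle Ia and II afferents enter through Poisson rate encoders.

Two circuit variants are built from the muscle-pair relation table
(antagonist / synergist / partial-synergist):

* ``complete`` — 36 neurons, 12 afferent encoders, exactly 150 connections
  realising the stretch-reflex, propriospinal, Ia-inhibitory and Renshaw
  pathways;
* ``simple``  — alpha and Renshaw pools only (12 neurons, no afferents),
  exactly the 42-connection Renshaw core of the complete variant.

Excitatory connections start at weight 5.0 (bounds [0, 10]), inhibitory at
-5.0 ([-10, 0]); partial-synergist connections are "flexible": they start
at 2.0 and may be optimised to either sign ([-10, 10]).  Every connection
has a 1 ms synaptic delay.  Weights are peak postsynaptic-current
amplitudes in pA, scaled at delivery by a global synaptic gain ``syn_gain``
(not part of the optimised vector).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import expm

from ._kernels import lif_window_kernel

__all__ = [
    "NEURON_TYPES",
    "SIMPLE_TYPES",
    "DEFAULT_RELATIONS",
    "NeuronParams",
    "ConnectionSpec",
    "Connectome",
    "SpikeRecord",
    "CircuitState",
    "build_connectome",
    "apply_weight_vector",
    "simulate_window",
]

from .mtu import MUSCLES

NEURON_TYPES = ("alpha", "gd", "gs", "IaIN", "PN", "R")
SIMPLE_TYPES = ("alpha", "R")
AFFERENT_TYPES = ("Ia", "II")

#: symmetric muscle-pair relations of the six-muscle arm
DEFAULT_RELATIONS = {
    "ANT": [("MEF", "MEE"), ("BEFSA", "BEESR"), ("MSA", "MSR")],
    "SYN": [("BEFSA", "MEF"), ("BEFSA", "MSA"), ("BEESR", "MEE"), ("BEESR", "MSR")],
    "SYNp": [("MEF", "MSA"), ("MEF", "MSR"), ("MEE", "MSA"), ("MEE", "MSR")],
}

_SIGN_INIT = {"excitatory": 5.0, "inhibitory": -5.0, "flexible": 2.0}
_SIGN_BOUNDS = {"excitatory": (0.0, 10.0), "inhibitory": (-10.0, 0.0),
                "flexible": (-10.0, 10.0)}

# normative connection table: (pre type, post type, scope, sign class)
_AFFERENT_RULES = [                      # complete variant only — 38 edges
    ("Ia", "alpha", "HOM", "excitatory"),
    ("Ia", "alpha", "SYN", "excitatory"),
    ("II", "alpha", "HOM", "excitatory"),
    ("Ia", "IaIN", "HOM", "excitatory"),
    ("Ia", "PN", "HOM", "excitatory"),
    ("II", "PN", "HOM", "excitatory"),
]
_INTERNEURON_RULES = [                   # complete variant only — 70 edges
    ("IaIN", "alpha", "ANT", "inhibitory"),
    ("IaIN", "IaIN", "ANT", "inhibitory"),
    ("IaIN", "alpha", "SYNp", "flexible"),
    ("PN", "alpha", "HOM", "excitatory"),
    ("PN", "alpha", "ANT", "inhibitory"),
    ("PN", "alpha", "SYNp", "flexible"),
    ("PN", "gd", "HOM", "excitatory"),
    ("PN", "gs", "HOM", "excitatory"),
    ("R", "IaIN", "ANT", "inhibitory"),
    ("R", "gd", "HOM", "inhibitory"),
    ("R", "gs", "HOM", "inhibitory"),
]
_RENSHAW_RULES = [                       # both variants — 42 edges
    ("alpha", "R", "HOM", "excitatory"),
    ("alpha", "R", "SYN", "excitatory"),
    ("R", "alpha", "HOM", "inhibitory"),
    ("R", "alpha", "SYN", "inhibitory"),
    ("R", "R", "ANT", "inhibitory"),
    ("R", "R", "SYNp", "flexible"),
]


@dataclass
class NeuronParams:
    """LIF neuron with alpha-shaped synaptic currents (pF / ms / mV / pA)."""

    C_m: float = 250.0
    tau_m: float = 10.0
    E_L: float = -70.0
    V_th: float = -55.0
    V_reset: float = -70.0
    t_ref: float = 2.0
    tau_syn_ex: float = 2.0
    tau_syn_in: float = 2.0
    I_e: float = 380.0
    syn_gain: float = 20.0   # global multiplier applied to weights at delivery

    def __post_init__(self) -> None:
        if self.V_th <= self.V_reset:
            raise ValueError("V_th must exceed V_reset")
        if min(self.tau_m, self.t_ref, self.tau_syn_ex, self.tau_syn_in) <= 0:
            raise ValueError("time constants must be positive")

    def propagator(self, dt_ms: float, *, euler: bool = False) -> np.ndarray:
        """Affine propagator over one step for the linear subthreshold state
        x = (y1e, y2e, y1i, y2i, V, 1).  Exact (matrix exponential) by
        default; ``euler=True`` returns the forward-Euler map I + A dt used
        by the validation integrator."""
        A = np.zeros((6, 6))
        A[0, 0] = -1.0 / self.tau_syn_ex
        A[1, 0] = 1.0
        A[1, 1] = -1.0 / self.tau_syn_ex
        A[2, 2] = -1.0 / self.tau_syn_in
        A[3, 2] = 1.0
        A[3, 3] = -1.0 / self.tau_syn_in
        A[4, 1] = 1.0 / self.C_m
        A[4, 3] = 1.0 / self.C_m
        A[4, 4] = -1.0 / self.tau_m
        A[4, 5] = self.I_e / self.C_m + self.E_L / self.tau_m
        if euler:
            return np.eye(6) + A * dt_ms
        return expm(A * dt_ms)


@dataclass
class ConnectionSpec:
    pre: str
    post: str
    scope: str            # HOM | ANT | SYN | SYNp
    sign_class: str       # excitatory | inhibitory | flexible
    weight: float
    bounds: tuple[float, float]
    delay: float = 1.0    # ms

    def clamp(self, w: float) -> float:
        return float(min(max(w, self.bounds[0]), self.bounds[1]))


class SpikeRecord(NamedTuple):
    unit: str
    t: float   # seconds


@dataclass
class Connectome:
    variant: str
    units: list[str]
    encoders: list[str]
    connections: list[ConnectionSpec]
    neuron_params: NeuronParams = field(default_factory=NeuronParams)

    @property
    def n_neurons(self) -> int:
        return len(self.units)

    def unit_index(self, label: str) -> int:
        all_units = self.units + self.encoders
        return all_units.index(label)

    def weight_vector(self) -> np.ndarray:
        return np.array([c.weight for c in self.connections])

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([c.bounds[0] for c in self.connections])
        hi = np.array([c.bounds[1] for c in self.connections])
        return lo, hi

    def compiled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR-style adjacency (by presynaptic unit) for the kernel:
        (conn_start, conn_post, conn_winc) with the alpha-current increment
        syn_gain * w * e / tau_syn already folded into the weight."""
        n_units = len(self.units) + len(self.encoders)
        idx = {u: i for i, u in enumerate(self.units + self.encoders)}
        order = sorted(range(len(self.connections)),
                       key=lambda k: idx[self.connections[k].pre])
        start = np.zeros(n_units + 1, dtype=np.int64)
        post = np.empty(len(order), dtype=np.int64)
        winc = np.empty(len(order))
        p = self.neuron_params
        for r, k in enumerate(order):
            c = self.connections[k]
            start[idx[c.pre] + 1] += 1
            post[r] = idx[c.post]
            tau = p.tau_syn_ex if c.weight >= 0 else p.tau_syn_in
            winc[r] = p.syn_gain * c.weight * math.e / tau
        return np.cumsum(start), post, winc


def _partner_map(relations: dict[str, list[tuple[str, str]]]) -> dict[str, dict[str, list[str]]]:
    """Expand symmetric relation pairs into per-muscle partner lists and
    reject inconsistent tables (self-relations or overlapping pairs)."""
    seen: set[frozenset] = set()
    out: dict[str, dict[str, list[str]]] = {s: {m: [] for m in MUSCLES}
                                            for s in ("ANT", "SYN", "SYNp")}
    for scope, pairs in relations.items():
        if scope not in out:
            raise ValueError(f"unknown relation scope {scope!r}")
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-relation {a}-{b}")
            if a not in MUSCLES or b not in MUSCLES:
                raise ValueError(f"unknown muscle in pair {a}-{b}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"overlapping relation for pair {a}-{b}")
            seen.add(key)
            out[scope][a].append(b)
            out[scope][b].append(a)
    for scope in out:  # canonical partner ordering
        for m in MUSCLES:
            out[scope][m].sort(key=MUSCLES.index)
    return out


def build_connectome(variant: str = "complete",
                     relations: dict[str, list[tuple[str, str]]] | None = None,
                     neuron_params: NeuronParams | None = None) -> Connectome:
    """Instantiate the spinal connectome for one circuit variant.

    Connections are emitted in canonical order: afferent block, then
    interneuronal block, then Renshaw core; within each rule, muscles in
    MEF..MSR order; within a muscle, partners in muscle order.  This order
    defines the layout of the optimised weight vector.
    """
    if variant not in ("complete", "simple"):
        raise ValueError("variant must be 'complete' or 'simple'")
    partners = _partner_map(relations or DEFAULT_RELATIONS)

    types = NEURON_TYPES if variant == "complete" else SIMPLE_TYPES
    units = [f"{t}_{m}" for t in types for m in MUSCLES]
    encoders = ([f"{t}_{m}" for t in AFFERENT_TYPES for m in MUSCLES]
                if variant == "complete" else [])

    rules = (_AFFERENT_RULES + _INTERNEURON_RULES + _RENSHAW_RULES
             if variant == "complete" else _RENSHAW_RULES)
    conns: list[ConnectionSpec] = []
    for pre_t, post_t, scope, sign in rules:
        for m in MUSCLES:
            targets = [m] if scope == "HOM" else partners[scope][m]
            for tgt in targets:
                conns.append(ConnectionSpec(
                    pre=f"{pre_t}_{m}", post=f"{post_t}_{tgt}", scope=scope,
                    sign_class=sign, weight=_SIGN_INIT[sign],
                    bounds=_SIGN_BOUNDS[sign]))
    return Connectome(variant=variant, units=units, encoders=encoders,
                      connections=conns,
                      neuron_params=neuron_params or NeuronParams())


def apply_weight_vector(c: Connectome, w: Sequence[float]) -> Connectome:
    """Return a connectome with weights set to ``w`` (canonical connection
    order), each clamped to its per-connection bounds."""
    w = np.asarray(w, dtype=float)
    if len(w) != len(c.connections):
        raise ValueError(f"expected {len(c.connections)} weights, got {len(w)}")
    new = [replace(ci, weight=ci.clamp(wi)) for ci, wi in zip(c.connections, w)]
    return replace(c, connections=new)


@dataclass
class CircuitState:
    """Continuous neural state persisting across exchange windows."""

    x: np.ndarray          # (5, n) = y1e, y2e, y1i, y2i, V
    refrac: np.ndarray     # (n,) remaining refractory steps
    buf_e: np.ndarray      # (delay+1, n) scheduled excitatory increments
    buf_i: np.ndarray
    ptr: int = 0

    @classmethod
    def initial(cls, c: Connectome, delay_steps: int) -> "CircuitState":
        n = c.n_neurons
        x = np.zeros((5, n))
        x[4] = c.neuron_params.E_L
        return cls(x=x, refrac=np.zeros(n, dtype=np.int64),
                   buf_e=np.zeros((delay_steps + 1, n)),
                   buf_i=np.zeros((delay_steps + 1, n)))


def simulate_window(c: Connectome, rates: Sequence[float], t0: float,
                    duration: float, rng: np.random.Generator,
                    state: CircuitState | None = None,
                    integrator: str = "exact", dt_ms: float = 0.1
                    ) -> tuple[list[SpikeRecord], CircuitState]:
    """Clock-driven simulation of one exchange window.

    ``rates`` are the Poisson encoder rates (pulses/s) in encoder order
    (Ia x 6, II x 6), held constant for the window (zero-order hold).
    Returns the spikes emitted during [t0, t0 + duration) and the updated
    neural state.  ``integrator='euler'`` runs the forward-Euler validation
    scheme at dt = 0.01 ms.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("encoder rates must be non-negative")
    if len(rates) != len(c.encoders):
        raise ValueError(f"expected {len(c.encoders)} encoder rates")
    p = c.neuron_params
    if integrator == "euler":
        dt_ms = 0.01
    elif integrator != "exact":
        raise ValueError("integrator must be 'exact' or 'euler'")
    delay_steps = int(round(1.0 / dt_ms))
    n_steps = int(round(duration * 1e3 / dt_ms))
    if state is None:
        state = CircuitState.initial(c, delay_steps)
    P = p.propagator(dt_ms, euler=(integrator == "euler"))
    start, post, winc = c.compiled()
    unif = rng.random((n_steps, max(1, len(c.encoders))))
    cap = (c.n_neurons + len(c.encoders)) * (n_steps + 1)
    out_unit = np.empty(cap, dtype=np.int64)
    out_step = np.empty(cap, dtype=np.int64)
    nsp, state.ptr = lif_window_kernel(
        P, state.x, state.refrac, state.buf_e, state.buf_i, state.ptr,
        start, post, winc, rates * dt_ms * 1e-3, unif,
        n_steps, delay_steps, p.V_th, p.V_reset,
        int(round(p.t_ref / dt_ms)), c.n_neurons, out_unit, out_step)
    if not np.all(np.isfinite(state.x)):
        raise FloatingPointError("non-finite neural state")
    labels = c.units + c.encoders
    spikes = [SpikeRecord(labels[out_unit[i]],
                          t0 + (out_step[i] + 1) * dt_ms * 1e-3)
              for i in range(nsp)]
    return spikes, state
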