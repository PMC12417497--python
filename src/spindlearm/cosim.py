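"""Lockstep closed loop between the spiking circuit and the arm plant.

One 0.8 s reaching episode is split into eight 0.1 s exchange windows.  In
each window the spiking circuit is advanced first, using the afferent
encoder rates fixed at the window start; the alpha and gamma motoneuron
spikes it emits are converted to fiber stimulation traces and drive the
mechanical plant over the same interval; at the window end the spindles'
instantaneous Ia/II rates become the encoder rates of the next window.
Afferent information generated in window ``w`` can therefore influence
spiking only from window ``w + 1`` — the exchange latency of the original
two-simulator co-simulation is preserved by construction.

Spike-to-stimulation conversion: the stimulation jumps to 1 at each spike
(all-or-nothing, non-additive reset) and decays as exp(-(t - t_spike)/tau)
with tau = 10 ms between spikes.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._kernels import N_STATE, _IL, mech_window_kernel, sample_aux
from .arm import ArmParams, JointState, forward_kinematics
from .circuit import CircuitState, Connectome, SpikeRecord, simulate_window
from .mtu import MUSCLES, MTUParams, default_muscles, pack_params
from .spindle import SpindleParams, pack_spindle

__all__ = [
    "TAU_U",
    "Scenario",
    "EpisodeResult",
    "spike_to_stimulation",
    "run_episode",
    "passive_episode",
]

TAU_U = 0.01  # s, stimulation decay constant


@dataclass(frozen=True)
class Scenario:
    """Circuit variant x mass perturbation x reach target."""

    circuit: str = "complete"
    perturbed: bool = False
    target: str = "T1"
    episode_s: float = 0.8
    exchange_s: float = 0.1

    def __post_init__(self) -> None:
        if self.circuit not in ("complete", "simple"):
            raise ValueError("circuit must be 'complete' or 'simple'")
        n = self.episode_s / self.exchange_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("exchange interval must divide episode length")

    @property
    def n_exchanges(self) -> int:
        return int(round(self.episode_s / self.exchange_s))

    @property
    def m_add(self) -> float:
        return 1.0 if self.perturbed else 0.0


@dataclass
class EpisodeResult:
    """Logs of one closed-loop episode on the shared 1 ms time base."""

    t: np.ndarray                # (n,)
    joints: np.ndarray           # (n, 4) psi, phi, dpsi, dphi
    hand: np.ndarray             # (n, 2)
    u_alpha: np.ndarray          # (n, 6)
    activation: np.ndarray       # (n, 6)
    l_ce: np.ndarray             # (n, 6)
    force: np.ndarray            # (n, 6)
    ia: np.ndarray               # (n, 6) pulses/s
    ii: np.ndarray               # (n, 6)
    spikes: list[SpikeRecord]
    encoder_rates: np.ndarray    # (n_exchanges, n_encoders) zero-order hold
    n_exchanges: int
    cost: float | None = None
    meta: dict = field(default_factory=dict)


def spike_to_stimulation(spike_times: Sequence[float], grid: np.ndarray,
                         tau: float = TAU_U, t_last: float | None = None
                         ) -> np.ndarray:
    """Fiber stimulation on ``grid`` from an ordered spike-time list.

    ``u`` is zero before the first spike, jumps to 1 at each spike time and
    decays exponentially with time constant ``tau``; a new spike resets the
    trace to 1 rather than summing.  ``t_last`` carries the most recent
    spike of an earlier window so traces stay continuous across windows.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size and np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted")
    grid = np.asarray(grid, dtype=float)
    u = np.zeros(len(grid))
    idx = np.searchsorted(st, grid, side="right") - 1
    has = idx >= 0
    u[has] = np.exp(-(grid[has] - st[idx[has]]) / tau)
    if t_last is not None:
        u[~has] = np.exp(-(grid[~has] - t_last) / tau)
    return u


def _initial_state(muscles: dict[str, MTUParams]) -> np.ndarray:
    y = np.zeros(N_STATE)
    y[0] = 0.0
    y[1] = math.pi / 2.0
    for m, name in enumerate(MUSCLES):
        y[_IL + m] = muscles[name].l_ce_opt
    return y


def _weight_hash(c: Connectome) -> str:
    return hashlib.sha1(c.weight_vector().tobytes()).hexdigest()[:12]


def run_episode(c: Connectome, scenario: Scenario, seed: int,
                arm_params: ArmParams | None = None,
                muscles: dict[str, MTUParams] | None = None,
                spindle_params: SpindleParams | None = None,
                h: float = 1e-4, sample_dt: float = 1e-3,
                encoder_rate_mode: str = "instant") -> EpisodeResult:
    """Run one closed-loop episode and return its logs.

    The arm starts at the central posture (psi = 0, phi = 90 deg) at rest,
    muscles at the activation floor with slack tendons, stimulation zero,
    and encoder rates zero (no afferent data exists before the first
    exchange).  ``encoder_rate_mode`` selects what is handed over at each
    exchange: the spindles' instantaneous rates at the exchange instant
    (default) or their mean over the elapsed window.  Identical
    (connectome, scenario, seed) yield bit-identical results.
    """
    if encoder_rate_mode not in ("instant", "mean"):
        raise ValueError("encoder_rate_mode must be 'instant' or 'mean'")
    if c.variant != scenario.circuit:
        raise ValueError(f"connectome variant {c.variant!r} does not match "
                         f"scenario circuit {scenario.circuit!r}")
    arm = arm_params or ArmParams()
    if arm.m_add != scenario.m_add:
        arm = replace(arm, m_add=scenario.m_add)
    muscles = muscles or default_muscles()
    sp = pack_spindle(spindle_params or SpindleParams())
    A = arm.packed()
    Pm = pack_params(muscles)

    n_w = scenario.n_exchanges
    steps_w = int(round(scenario.exchange_s / h))
    samples_w = int(round(scenario.exchange_s / sample_dt))
    n_samples = n_w * samples_w + 1
    n_enc = len(c.encoders)

    rng = np.random.default_rng(seed)
    y = _initial_state(muscles)
    states = np.zeros((n_samples, 4))
    auxlog = np.zeros((n_samples, 30))
    u_alpha = np.zeros((n_samples, 6))
    states[0, :4] = y[:4]

    zeros6 = np.zeros(6)
    auxlog[0] = sample_aux(y, zeros6, zeros6, zeros6, A, Pm, sp)

    # per-stream carry of the most recent spike time (alpha, gd, gs x 6)
    t_last: dict[str, float | None] = {
        f"{t}_{m}": None for t in ("alpha", "gd", "gs") for m in MUSCLES}

    spikes_all: list[SpikeRecord] = []
    enc_rates = np.zeros((n_w, n_enc))
    rates = np.zeros(n_enc)
    neural: CircuitState | None = None

    half = np.arange(2 * steps_w + 1) * (0.5 * h)
    ms_rows = np.arange(0, 2 * steps_w + 1, int(round(sample_dt / h)) * 2)

    for w in range(n_w):
        t0 = w * scenario.exchange_s
        if n_enc:
            enc_rates[w] = rates
        win_spikes, neural = simulate_window(
            c, rates, t0, scenario.exchange_s, rng, neural)
        spikes_all.extend(win_spikes)

        per_unit: dict[str, list[float]] = {}
        for rec in win_spikes:
            per_unit.setdefault(rec.unit, []).append(rec.t)

        grid = t0 + half
        uh = {}
        for kind in ("alpha", "gd", "gs"):
            tr = np.empty((len(grid), 6))
            for m, name in enumerate(MUSCLES):
                stream = f"{kind}_{name}"
                st = per_unit.get(stream, [])
                tr[:, m] = spike_to_stimulation(st, grid, TAU_U, t_last[stream])
                if st:
                    t_last[stream] = st[-1]
            uh[kind] = tr

        s0 = w * samples_w
        mech_window_kernel(y, uh["alpha"], uh["gd"], uh["gs"], A, Pm, sp,
                           h, steps_w, int(round(sample_dt / h)),
                           states, auxlog, s0)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("non-finite plant state during episode")
        u_alpha[s0 + 1:s0 + samples_w + 1] = uh["alpha"][ms_rows[1:]]

        if n_enc:
            end = s0 + samples_w
            if encoder_rate_mode == "instant":
                # spindle rates at the exchange instant
                rates = np.concatenate([auxlog[end, 3::5], auxlog[end, 4::5]])
            else:
                win = auxlog[s0 + 1:end + 1]
                rates = np.concatenate([win[:, 3::5].mean(axis=0),
                                        win[:, 4::5].mean(axis=0)])

    t = np.arange(n_samples) * sample_dt
    hand = np.empty((n_samples, 2))
    for i in range(n_samples):
        _, hand[i] = forward_kinematics(JointState.from_array(states[i]), arm)

    return EpisodeResult(
        t=t, joints=states, hand=hand, u_alpha=u_alpha,
        activation=auxlog[:, 0::5], l_ce=auxlog[:, 2::5],
        force=auxlog[:, 1::5], ia=auxlog[:, 3::5], ii=auxlog[:, 4::5],
        spikes=spikes_all, encoder_rates=enc_rates, n_exchanges=n_w,
        meta={"seed": seed, "scenario": scenario,
              "weight_hash": _weight_hash(c)})


def passive_episode(scenario: Scenario,
                    arm_params: ArmParams | None = None,
                    muscles: dict[str, MTUParams] | None = None,
                    spindle_params: SpindleParams | None = None,
                    h: float = 1e-4, sample_dt: float = 1e-3) -> EpisodeResult:
    """Mechanics-only oracle: one continuous integration of the passive
    plant (stimulation identically zero), without the windowed exchange
    machinery.  A zero-drive closed-loop episode must coincide with this.
    """
    arm = arm_params or ArmParams()
    if arm.m_add != scenario.m_add:
        arm = replace(arm, m_add=scenario.m_add)
    muscles = muscles or default_muscles()
    sp = pack_spindle(spindle_params or SpindleParams())
    A = arm.packed()
    Pm = pack_params(muscles)

    n_steps = int(round(scenario.episode_s / h))
    samples = int(round(scenario.episode_s / sample_dt))
    y = _initial_state(muscles)
    states = np.zeros((samples + 1, 4))
    auxlog = np.zeros((samples + 1, 30))
    states[0, :4] = y[:4]
    zeros6 = np.zeros(6)
    auxlog[0] = sample_aux(y, zeros6, zeros6, zeros6, A, Pm, sp)
    uh = np.zeros((2 * n_steps + 1, 6))
    mech_window_kernel(y, uh, uh, uh, A, Pm, sp, h, n_steps,
                       int(round(sample_dt / h)), states, auxlog, 0)
    t = np.arange(samples + 1) * sample_dt
    hand = np.empty((samples + 1, 2))
    for i in range(samples + 1):
        _, hand[i] = forward_kinematics(JointState.from_array(states[i]), arm)
    return EpisodeResult(
        t=t, joints=states, hand=hand,
        u_alpha=np.zeros((samples + 1, 6)),
        activation=auxlog[:, 0::5], l_ce=auxlog[:, 2::5],
        force=auxlog[:, 1::5], ia=auxlog[:, 3::5], ii=auxlog[:, 4::5],
        spikes=[], encoder_rates=np.zeros((scenario.n_exchanges, 0)),
        n_exchanges=scenario.n_exchanges, meta={"passive": True})
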