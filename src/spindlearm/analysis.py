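"""Result analysis and file plumbing.

Connection matrices (presynaptic x postsynaptic weights, with an explicit
no-connection marker distinct from a zero weight), spindle-afferent weight
histograms, reach-success reports, trajectory timing markers, weight-vector
CSV round-tripping, YAML configuration, and scripted fixtures for unit
tests (spike trains and length-ramp profiles).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .arm import ArmParams
from .circuit import Connectome, NeuronParams
from .cosim import EpisodeResult
from .learning import CostConfig, TargetSet, make_targets
from .mtu import MTUParams, default_muscles
from .spindle import SpindleParams

__all__ = [
    "ConnectionMatrix",
    "ReachReport",
    "connection_matrix",
    "connectome_from_matrix",
    "afferent_weight_histogram",
    "reach_report",
    "timing_markers",
    "fixtures",
    "export_weights",
    "import_weights",
    "SimConfig",
]

#: value marking "no connection" in exported matrices (a flexible synapse
#: can legitimately be optimised to exactly 0.0, so 0 is not usable)
NO_CONNECTION = np.nan


@dataclass
class ConnectionMatrix:
    values: np.ndarray       # (n_pre, n_post), NaN where no connection exists
    row_labels: list[str]    # presynaptic units (neurons, then afferents)
    col_labels: list[str]    # postsynaptic units (neurons only)

    @property
    def n_connections(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)


def connection_matrix(c: Connectome) -> ConnectionMatrix:
    """Weights arranged presynaptic x postsynaptic.

    Rows are the neuronal units in type order (alpha, gd, gs, IaIN, PN, R
    across the six muscles) followed by the Ia and II afferent encoders;
    columns are the neuronal units only.  Complete variant: 48 x 36;
    simple: 12 x 12.
    """
    rows = c.units + c.encoders
    cols = c.units
    ridx = {u: i for i, u in enumerate(rows)}
    cidx = {u: i for i, u in enumerate(cols)}
    M = np.full((len(rows), len(cols)), NO_CONNECTION)
    for conn in c.connections:
        M[ridx[conn.pre], cidx[conn.post]] = conn.weight
    return ConnectionMatrix(values=M, row_labels=rows, col_labels=cols)


def connectome_from_matrix(c: Connectome, m: ConnectionMatrix) -> Connectome:
    """Read weights back from a matrix (inverse of ``connection_matrix``)."""
    ridx = {u: i for i, u in enumerate(m.row_labels)}
    cidx = {u: i for i, u in enumerate(m.col_labels)}
    w = []
    for conn in c.connections:
        v = m.values[ridx[conn.pre], cidx[conn.post]]
        if np.isnan(v):
            raise ValueError(f"matrix lacks connection {conn.pre}->{conn.post}")
        w.append(v)
    new = [dataclasses.replace(ci, weight=float(wi))
           for ci, wi in zip(c.connections, w)]
    return dataclasses.replace(c, connections=new)


def afferent_weight_histogram(c: Connectome, bins: np.ndarray | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the spindle-afferent (Ia/II encoder) synaptic weights.

    Defaults to unit-width bins on [-10, 10].  Only meaningful for the
    complete variant — the simple circuit has no afferent connections.
    """
    if c.variant != "complete":
        raise ValueError("afferent histogram requires the complete variant")
    if bins is None:
        bins = np.arange(-10.0, 11.0, 1.0)
    w = np.array([conn.weight for conn in c.connections
                  if conn.pre.startswith(("Ia_", "II_"))])
    counts, edges = np.histogram(w, bins=bins)
    return counts, edges


@dataclass
class ReachReport:
    per_target: dict[str, dict]
    n_reached: int
    success_radius: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.per_target, orient="index")


def reach_report(results: dict[str, EpisodeResult | tuple[float, float]],
                 targets: TargetSet | None = None,
                 success_radius: float = 0.05) -> ReachReport:
    """Per-target endpoint errors and success flags.

    ``results`` maps target ids to episode results (or bare final hand
    positions).  A target counts as reached when the endpoint error is
    below ``success_radius`` (default: the 0.05 m cost-switch threshold).
    """
    targets = targets or make_targets()
    missing = set(targets.targets) - set(results)
    if missing:
        raise ValueError(f"missing results for targets {sorted(missing)}")
    per: dict[str, dict] = {}
    n_ok = 0
    for tid, tgt in targets:
        r = results[tid]
        if isinstance(r, EpisodeResult):
            fx, fz = float(r.hand[-1, 0]), float(r.hand[-1, 1])
            cost = r.cost
        else:
            fx, fz = float(r[0]), float(r[1])
            cost = None
        err = float(np.hypot(fx - tgt.x, fz - tgt.z))
        ok = err < success_radius
        n_ok += int(ok)
        per[tid] = {"final_x": fx, "final_z": fz, "error_m": err,
                    "success": ok, "cost": cost}
    return ReachReport(per_target=per, n_reached=n_ok,
                       success_radius=success_radius)


def timing_markers(trajectory: np.ndarray, marker_dt: float = 0.05,
                   sample_dt: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Marker points every 50 ms along a 1 ms-sampled hand trajectory.

    An 0.8 s trajectory (801 points) yields 17 markers (16 gaps).  Returns
    (sample indices, marker points).
    """
    traj = np.asarray(trajectory)
    step = int(round(marker_dt / sample_dt))
    if (len(traj) - 1) % step != 0:
        raise ValueError("trajectory length does not fit the marker grid")
    idx = np.arange(0, len(traj), step)
    return idx, traj[idx]


def fixtures(kind: str, params: dict | None = None, seed: int = 0):
    """Scripted test inputs: spike trains and length-ramp profiles.

    ``spike_train``: periodic (default) or Poisson spike times over a
    duration; ``ramp_profile``: normalized-length ramp-and-hold with its
    rate, on a 1 ms grid.
    """
    params = dict(params or {})
    if kind == "spike_train":
        rate = params.get("rate", 20.0)
        duration = params.get("duration", 0.8)
        mode = params.get("mode", "periodic")
        if mode == "periodic":
            return np.arange(1, int(np.floor(rate * duration + 1e-9)) + 1) / rate
        if mode == "poisson":
            rng = np.random.default_rng(seed)
            isis = rng.exponential(1.0 / rate, size=int(rate * duration * 4) + 16)
            t = np.cumsum(isis)
            return t[t < duration]
        raise ValueError(f"unknown spike_train mode {mode!r}")
    if kind == "ramp_profile":
        start = params.get("start", 0.95)
        stop = params.get("stop", 1.05)
        ramp_s = params.get("ramp_s", 0.2)
        hold_s = params.get("hold_s", 0.2)
        dt = params.get("dt", 1e-3)
        n_r = int(round(ramp_s / dt))
        n_h = int(round(hold_s / dt))
        t = np.arange(n_r + n_h + 1) * dt
        lam = np.concatenate([np.linspace(start, stop, n_r + 1),
                              np.full(n_h, stop)])
        dlam = np.gradient(lam, dt)
        return t, lam, dlam
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------- file I/O

def export_weights(c: Connectome, path) -> None:
    """Write the weight vector with its canonical connection layout."""
    rows = [{"index": i, "pre": conn.pre, "post": conn.post,
             "scope": conn.scope, "sign_class": conn.sign_class,
             "lo": conn.bounds[0], "hi": conn.bounds[1],
             "weight": conn.weight}
            for i, conn in enumerate(c.connections)]
    # %.17g preserves doubles exactly across the CSV round trip
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def import_weights(path, c: Connectome | None = None) -> np.ndarray:
    """Read a weight vector; validates the layout if a connectome is given."""
    df = pd.read_csv(path, float_precision="round_trip")
    df = df.sort_values("index")
    if c is not None:
        for i, conn in enumerate(c.connections):
            if df.iloc[i]["pre"] != conn.pre or df.iloc[i]["post"] != conn.post:
                raise ValueError(f"weight file row {i} does not match the "
                                 f"connectome's canonical order")
    return df["weight"].to_numpy()


@dataclass
class SimConfig:
    """Every tunable of the simulator in one structured document."""

    arm: ArmParams = field(default_factory=ArmParams)
    muscles: dict[str, MTUParams] = field(default_factory=default_muscles)
    spindle: SpindleParams = field(default_factory=SpindleParams)
    neurons: NeuronParams = field(default_factory=NeuronParams)
    cost: CostConfig = field(default_factory=CostConfig)
    optimizer: dict = field(default_factory=lambda: {
        "popsize": 150, "max_iters": 1000, "sigma0": 2.0})

    def to_yaml(self, path) -> None:
        doc = {
            "arm": dataclasses.asdict(self.arm),
            "muscles": {k: dataclasses.asdict(v) for k, v in self.muscles.items()},
            "spindle": dataclasses.asdict(self.spindle),
            "neurons": dataclasses.asdict(self.neurons),
            "cost": dataclasses.asdict(self.cost),
            "optimizer": dict(self.optimizer),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(doc), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            arm=ArmParams(**_tupled(doc["arm"], ("shoulder_limits", "elbow_limits"))),
            muscles={k: MTUParams(**v) for k, v in doc["muscles"].items()},
            spindle=SpindleParams(**_tupled(doc["spindle"], ("K_L", "K_V", "beta_a"))),
            neurons=NeuronParams(**doc["neurons"]),
            cost=CostConfig(**doc["cost"]),
            optimizer=dict(doc["optimizer"]),
        )


def _plain(x):
    if isinstance(x, dict):
        return {k: _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def _tupled(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d:
            d[k] = tuple(d[k])
    return d
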