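"""Synaptic-weight learning for the center-out reaching task.

The reach target set is a 3x3 grid of hand positions spaced 0.1 m around
the central start position (0.33, -0.33) m, minus the center itself —
eight peripheral targets T1..T8, numbered row-major with the top row
first.

The cost of a candidate weight vector is the switched Euclidean objective:
while the trajectory still ends far from the target (|x_end - x_ref| or
|z_end - z_ref| >= 0.05 m) the cost sums the distances of *all* trajectory
points to the target, pulling the whole path toward it; once the endpoint
is within the 0.05 m box the cost switches to the endpoint distance alone,
forcing the final hand position onto the target.

Learning is covariance-matrix-adaptation evolution strategy (CMA-ES):
a derivative-free stochastic optimizer standing in for trial-and-error
motor learning.  Box bounds per synapse are enforced by projection before
evaluation.  Per-candidate episode seeds are derived deterministically
from (run seed, generation, candidate), so runs are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .arm import CartesianPoint
from .circuit import Connectome, apply_weight_vector, build_connectome
from .cosim import Scenario, run_episode

__all__ = [
    "TargetSet",
    "CostConfig",
    "OptimizationResult",
    "make_targets",
    "reach_cost",
    "CMAES",
    "optimize_weights",
]


@dataclass(frozen=True)
class TargetSet:
    center: CartesianPoint
    spacing: float
    targets: dict[str, CartesianPoint]

    def __getitem__(self, tid: str) -> CartesianPoint:
        return self.targets[tid]

    def __len__(self) -> int:
        return len(self.targets)

    def __iter__(self):
        return iter(self.targets.items())


# row-major grid offsets, top row first, center excluded
_GRID_OFFSETS = [(-1, 1), (0, 1), (1, 1), (-1, 0), (1, 0),
                 (-1, -1), (0, -1), (1, -1)]


def make_targets(center: CartesianPoint = CartesianPoint(0.33, -0.33),
                 spacing: float = 0.1) -> TargetSet:
    """Eight peripheral targets on the 3x3 grid around ``center``."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    targets = {
        f"T{i + 1}": CartesianPoint(center.x + dx * spacing,
                                    center.z + dz * spacing)
        for i, (dx, dz) in enumerate(_GRID_OFFSETS)
    }
    return TargetSet(center=center, spacing=spacing, targets=targets)


@dataclass(frozen=True)
class CostConfig:
    switch_threshold: float = 0.05  # m, per-coordinate switch box

    def __post_init__(self) -> None:
        if self.switch_threshold <= 0:
            raise ValueError("switch threshold must be positive")


def reach_cost(trajectory: np.ndarray, target: CartesianPoint,
               cfg: CostConfig = CostConfig()) -> float:
    """Switched reach cost of a hand trajectory (rows of x, z in m)."""
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.size == 0:
        raise ValueError("empty trajectory")
    dx = traj[-1, 0] - target.x
    dz = traj[-1, 1] - target.z
    if abs(dx) < cfg.switch_threshold and abs(dz) < cfg.switch_threshold:
        return float(math.hypot(dx, dz))
    return float(np.sum(np.hypot(traj[:, 0] - target.x, traj[:, 1] - target.z)))


class CMAES:
    """(mu/mu_w, lambda) covariance-matrix-adaptation evolution strategy.

    Standard formulation with weighted recombination, cumulative step-size
    adaptation and rank-one plus rank-mu covariance updates.  Box bounds
    are handled by projecting sampled candidates onto the box before
    evaluation (the repaired candidates enter the distribution update).
    """

    def __init__(self, x0: Sequence[float], sigma0: float,
                 popsize: int | None = None, seed: int = 0,
                 bounds: tuple[np.ndarray, np.ndarray] | None = None):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.n = len(self.mean)
        self.sigma = float(sigma0)
        self.lam = popsize or 4 + int(3 * math.log(self.n))
        if self.lam < 4:
            raise ValueError("population size must be at least 4")
        self.bounds = bounds
        self.rng = np.random.default_rng(seed)

        mu = self.lam // 2
        w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
        self.w = w / w.sum()
        self.mu = mu
        self.mueff = 1.0 / np.sum(self.w ** 2)
        n, mueff = self.n, self.mueff
        self.cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
        self.cs = (mueff + 2) / (n + mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + mueff)
        self.cmu = min(1 - self.c1,
                       2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
        self.damps = (1 + 2 * max(0.0, math.sqrt((mueff - 1) / (n + 1)) - 1)
                      + self.cs)
        self.chiN = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

        self.C = np.eye(n)
        self.ps = np.zeros(n)
        self.pc = np.zeros(n)
        self._decompose()
        self.generation = 0

    def _decompose(self) -> None:
        C = (self.C + self.C.T) / 2
        d, B = np.linalg.eigh(C)
        self.D = np.sqrt(np.clip(d, 1e-20, None))
        self.B = B

    def ask(self) -> np.ndarray:
        """Sample a population of candidates (projected onto the bounds)."""
        z = self.rng.standard_normal((self.lam, self.n))
        X = self.mean + self.sigma * (z * self.D) @ self.B.T
        if self.bounds is not None:
            np.clip(X, self.bounds[0], self.bounds[1], out=X)
        return X

    def tell(self, X: np.ndarray, costs: Sequence[float]) -> None:
        """Update the search distribution from evaluated candidates."""
        costs = np.asarray(costs, dtype=float)
        order = np.argsort(costs)
        Xs = X[order[:self.mu]]
        old_mean = self.mean
        self.mean = self.w @ Xs
        y_w = (self.mean - old_mean) / self.sigma

        Cinv_half = self.B @ np.diag(1.0 / self.D) @ self.B.T
        self.ps = ((1 - self.cs) * self.ps
                   + math.sqrt(self.cs * (2 - self.cs) * self.mueff)
                   * Cinv_half @ y_w)
        hsig = (np.linalg.norm(self.ps)
                / math.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
                / self.chiN) < 1.4 + 2 / (self.n + 1)
        self.pc = ((1 - self.cc) * self.pc
                   + hsig * math.sqrt(self.cc * (2 - self.cc) * self.mueff) * y_w)

        Y = (Xs - old_mean) / self.sigma
        rank_mu = (Y * self.w[:, None]).T @ Y
        dh = (1 - hsig) * self.cc * (2 - self.cc)
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc) + dh * self.C)
                  + self.cmu * rank_mu)
        self.sigma *= math.exp((self.cs / self.damps)
                               * (np.linalg.norm(self.ps) / self.chiN - 1))
        self._decompose()
        self.generation += 1


@dataclass
class OptimizationResult:
    best_weights: np.ndarray
    best_cost: float
    history: np.ndarray      # best-ever cost per generation (non-increasing)
    n_evaluations: int
    seed: int
    scenario: Scenario | None = None


def episode_seed(seed: int, generation: int, candidate: int) -> int:
    """Deterministic per-candidate episode seed, kept below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(generation, candidate))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def optimize_weights(scenario: Scenario, budget: tuple[int, int] = (150, 1000),
                     sigma0: float = 2.0, seed: int = 0,
                     connectome: Connectome | None = None,
                     targets: TargetSet | None = None,
                     cost_cfg: CostConfig = CostConfig(),
                     objective: Callable[[np.ndarray, int, int], float] | None = None,
                     ftarget: float = 1e-4,
                     callback: Callable[[int, float], None] | None = None,
                     ) -> OptimizationResult:
    """Optimize the spinal weight vector with CMA-ES.

    ``budget`` is (population size, maximum generations).  Each candidate
    is clamped to its per-connection bounds, applied to the connectome and
    scored by one closed-loop episode against the scenario's target; a
    failed episode scores +inf.  ``objective(w, generation, candidate)``
    replaces the episode cost (optimizer test hook).
    """
    pop, max_iters = budget
    if pop < 4 or max_iters < 1:
        raise ValueError("need population >= 4 and at least one generation")
    c = connectome or build_connectome(scenario.circuit)
    target = (targets or make_targets())[scenario.target]

    if objective is None:
        def objective(w: np.ndarray, gen: int, i: int) -> float:
            try:
                cw = apply_weight_vector(c, w)
                res = run_episode(cw, scenario, episode_seed(seed, gen, i))
                return reach_cost(res.hand, target, cost_cfg)
            except FloatingPointError:
                return float("inf")

    es = CMAES(c.weight_vector(), sigma0, popsize=pop, seed=seed,
               bounds=c.bounds_arrays())
    best_w = c.weight_vector()
    best_cost = float("inf")
    history = []
    n_evals = 0
    for gen in range(max_iters):
        X = es.ask()
        costs = np.array([objective(X[i], gen, i) for i in range(pop)])
        n_evals += pop
        es.tell(X, costs)
        i_best = int(np.argmin(costs))
        if costs[i_best] < best_cost:
            best_cost = float(costs[i_best])
            best_w = X[i_best].copy()
        history.append(best_cost)
        if callback is not None:
            callback(gen, best_cost)
        if best_cost < ftarget:
            break
    return OptimizationResult(best_weights=best_w, best_cost=best_cost,
                              history=np.array(history), n_evaluations=n_evals,
                              seed=seed, scenario=scenario)
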