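"""Baseline particle swarm optimisation over threshold space.

Particles carry real-valued positions in ``[LB, UB]^D`` with ``D`` equal to
the number of thresholds; a position is decoded to a strictly increasing
integer threshold tuple before each fitness evaluation.  The classic update
is

.. math::

    v \\leftarrow \\omega v + c_1 r_1 (p_{best} - x) + c_2 r_2 (g_{best} - x),
    \\qquad x \\leftarrow x + v

with ``r_1, r_2`` drawn independently per particle *and per dimension*,
velocities clamped to ``±v_max`` and positions clamped to the bounds.  The
objective (Kapur entropy) is maximised throughout.

Notes on choices the classic formulation leaves open:

* velocity is clamped at ``v_max = v_max_fraction * (UB - LB)``; the default
  fraction of 1.0 allows a particle to cross the whole box in one step —
  i.e. the update is effectively unclamped, as in the classic formulation —
  while still guarding against numeric runaway.  Tighter fractions are
  available but materially change the optimizer comparison: a strong clamp
  masks the premature-convergence weakness of the fixed-inertia baseline on
  wide 12-bit search ranges;
* out-of-bounds positions are clamped (not reflected) and the velocity is
  left unchanged;
* duplicate decoded thresholds are repaired, not rejected, so every particle
  stays evaluable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .histogram import GrayHistogram, KapurObjective, ThresholdSet

__all__ = [
    "SwarmConfig",
    "Swarm",
    "RunResult",
    "InfeasibleDimensionError",
    "init_swarm",
    "pso_step",
    "decode_position",
    "run_pso",
]


class InfeasibleDimensionError(ValueError):
    """More thresholds requested than distinct integer levels available."""


@dataclass
class SwarmConfig:
    """Hyperparameters shared by the baseline and CIWP optimizers.

    Defaults follow the standard comparison protocol for multilevel
    thresholding: 30 particles, 100 iterations, ``c1 = c2 = 1.5``; the
    baseline uses a fixed inertia ``omega = 0.8`` while the CIWP variant uses
    the complementary pair bounded by ``omega_min``/``omega_max`` and assigns
    the worst ``1 - rate`` fraction of the swarm to the opposition layer.
    """

    n_particles: int = 30
    n_iterations: int = 100
    n_thresholds: int = 2
    c1: float = 1.5
    c2: float = 1.5
    omega: float = 0.8
    omega_min: float = 0.5
    omega_max: float = 0.9
    rate: float = 0.9
    lower: float = 1.0
    upper: float = 255.0
    v_max_fraction: float = 1.0
    rol_per_dimension: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not self.lower < self.upper:
            raise ValueError("need lower < upper")
        if not 0 < self.omega_min <= self.omega_max:
            raise ValueError("need 0 < omega_min <= omega_max")
        if not 0 < self.rate <= 1:
            raise ValueError("rate must lie in (0, 1]")

    @property
    def v_max(self) -> float:
        return self.v_max_fraction * (self.upper - self.lower)

    @classmethod
    def for_levels(cls, levels: int, n_thresholds: int, **kwargs) -> "SwarmConfig":
        """Config with search bounds ``[1, L - 1]`` for an L-level histogram."""
        return cls(n_thresholds=n_thresholds, lower=1.0, upper=float(levels - 1), **kwargs)


@dataclass
class Swarm:
    """State of the population: positions, velocities and personal bests."""

    positions: np.ndarray  # (N, D)
    velocities: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    pbest_positions: np.ndarray  # (N, D)
    pbest_fitness: np.ndarray  # (N,)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def gbest_index(self) -> int:
        """Index of the all-time best particle (first occurrence on ties)."""
        return int(np.argmax(self.pbest_fitness))


@dataclass
class RunResult:
    """Outcome of an optimisation run.

    ``convergence`` holds the best-so-far fitness after each iteration and is
    non-decreasing by construction.
    """

    best_position: np.ndarray
    best_thresholds: ThresholdSet
    best_fitness: float
    convergence: np.ndarray

    def to_dict(self) -> dict:
        return {
            "best_thresholds": list(self.best_thresholds.values),
            "best_fitness": self.best_fitness,
            "convergence": [float(v) for v in self.convergence],
        }


def init_swarm(config: SwarmConfig, rng: np.random.Generator) -> Swarm:
    """Uniform random positions in the box and velocities in ``±v_max``."""
    n, d = config.n_particles, config.n_thresholds
    positions = rng.uniform(config.lower, config.upper, size=(n, d))
    velocities = rng.uniform(-config.v_max, config.v_max, size=(n, d))
    fitness = np.full(n, -np.inf)
    return Swarm(
        positions=positions,
        velocities=velocities,
        fitness=fitness,
        pbest_positions=positions.copy(),
        pbest_fitness=fitness.copy(),
    )


def pso_step(
    swarm: Swarm,
    gbest_position: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator,
    freeze: int | None = None,
) -> None:
    """One in-place velocity/position update of the whole swarm.

    ``freeze`` optionally exempts one particle (elitism): its position and
    velocity are left untouched while the rest of the swarm updates with the
    same random draws.
    """
    n, d = swarm.positions.shape
    r1 = rng.random((n, d))
    r2 = rng.random((n, d))
    attraction = config.c1 * r1 * (swarm.pbest_positions - swarm.positions) + (
        config.c2 * r2 * (gbest_position - swarm.positions)
    )
    new_v = np.clip(config.omega * swarm.velocities + attraction, -config.v_max, config.v_max)
    new_x = np.clip(swarm.positions + new_v, config.lower, config.upper)
    mask = np.ones(n, dtype=bool)
    if freeze is not None:
        mask[freeze] = False
    swarm.velocities[mask] = new_v[mask]
    swarm.positions[mask] = new_x[mask]


def decode_position(position: Sequence[float] | np.ndarray, levels: int) -> ThresholdSet:
    """Map a real position vector to a valid strictly increasing threshold set.

    Components are rounded half-up and sorted; duplicates are repaired by
    pushing the later duplicate to the smallest unused larger integer, and by
    a backward pass pulling values down when the ceiling ``L - 1`` is hit.
    """
    pos = np.asarray(position, dtype=float)
    d = pos.shape[0]
    if d >= levels - 1:
        raise InfeasibleDimensionError(
            f"{d} thresholds cannot be strictly increasing within [1, {levels - 1}]"
        )
    vals = np.floor(np.sort(pos) + 0.5).astype(np.int64)
    vals = np.clip(vals, 1, levels - 1)
    for i in range(1, d):
        if vals[i] <= vals[i - 1]:
            vals[i] = vals[i - 1] + 1
    if vals[-1] > levels - 1:
        vals[-1] = levels - 1
        for i in range(d - 2, -1, -1):
            if vals[i] >= vals[i + 1]:
                vals[i] = vals[i + 1] - 1
    return ThresholdSet(values=tuple(int(v) for v in vals), levels=levels)


def _evaluate(swarm: Swarm, objective: KapurObjective) -> None:
    """Decode every particle and refresh ``swarm.fitness`` in place."""
    decoded = np.empty_like(swarm.positions, dtype=np.int64)
    for i in range(swarm.n_particles):
        decoded[i] = decode_position(swarm.positions[i], objective.levels).values
    swarm.fitness = objective.evaluate_many(decoded)


def _update_pbest(swarm: Swarm) -> None:
    improved = swarm.fitness > swarm.pbest_fitness
    swarm.pbest_positions[improved] = swarm.positions[improved]
    swarm.pbest_fitness[improved] = swarm.fitness[improved]


def make_objective(hist: GrayHistogram) -> KapurObjective:
    """Kapur-entropy objective bound to a histogram (prefix-sum accelerated)."""
    return KapurObjective(hist)


def run_pso(
    objective: KapurObjective,
    config: SwarmConfig,
    rng: np.random.Generator | None = None,
    elitism: bool = False,
) -> RunResult:
    """Maximise Kapur entropy with the baseline swarm for ``T`` iterations.

    Each iteration evaluates all particles, refreshes personal/global bests,
    records the best-so-far fitness and then applies :func:`pso_step`.  With
    ``elitism=True`` the current-iteration best particle (ties to the lowest
    index) is frozen during the step, matching the elite tier of the CIWP
    variant.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    swarm = init_swarm(config, rng)
    convergence = np.empty(config.n_iterations)
    for t in range(config.n_iterations):
        _evaluate(swarm, objective)
        _update_pbest(swarm)
        g = swarm.gbest_index()
        convergence[t] = swarm.pbest_fitness[g]
        freeze = int(np.argmax(swarm.fitness)) if elitism else None
        pso_step(swarm, swarm.pbest_positions[g], config, rng, freeze=freeze)
    g = swarm.gbest_index()
    best_pos = swarm.pbest_positions[g].copy()
    return RunResult(
        best_position=best_pos,
        best_thresholds=decode_position(best_pos, objective.levels),
        best_fitness=float(swarm.pbest_fitness[g]),
        convergence=convergence,
    )
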