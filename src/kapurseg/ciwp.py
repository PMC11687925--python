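"""Pyramid PSO with complementary inverse-sigmoid inertia weights (CIWP-PSO).

The variant modifies the classic swarm in two ways, both aimed at the much
larger search range of high-bit-depth (12-bit, L = 4096) images:

**Pyramid layering with random opposition learning.**  Each iteration the
swarm is sorted by fitness and split into three tiers: a single *elite*
(current best, frozen for the iteration), a *middle* tier following the
modified velocity update, and a *worst* tier of ``round((1 - rate) * N)``
particles that is teleported by random opposition learning (ROL)::

    P  <-  clip(LB + UB - r * P,  LB, UB),   r ~ Uniform[0, 1]

which mirrors poor solutions into the opposite region of the box and keeps
the population diverse.

**Complementary inertia weights.**  Each middle particle receives a pair of
weights driven by its fitness rank within the current swarm through a scaled
logit ("inverse sigmoid")::

    S(x)     = ln((s_x x + m_x) / (m_x - s_x x)) / s_y
    omega    = (omega_min + omega_max)/2 + (omega_max - omega_min) * S(x)
    omega_r  = (omega_min + omega_max)/2 - (omega_max - omega_min) * S(x)
    x        = (f - (f_best + f_worst)/2) / (f_best - f_worst)

so ``omega + omega_r == omega_min + omega_max`` by construction.  A fit
particle keeps momentum (large ``omega``) and damps its attraction terms
(small ``omega_r``, exploit); a poor one does the opposite (explore).  The
middle-tier update is::

    v <- omega(f) * v + omega_r(f) * (c1 r1 (pbest - x) + c2 r2 (gbest - x))
    x <- x + v

With the default shape parameters ``s_x = 0.96, s_y = 7.8, m_x = 0.5`` the
logit spans ``S(±0.5) ≈ ±0.499``, so the weights cover essentially the full
``[omega_min, omega_max]`` band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .histogram import KapurObjective
from .pso import (
    RunResult,
    Swarm,
    SwarmConfig,
    _evaluate,
    _update_pbest,
    decode_position,
    init_swarm,
)

__all__ = [
    "WeightParams",
    "LayerPartition",
    "partition_layers",
    "inverse_sigmoid",
    "complementary_weights",
    "rol_update",
    "ciwp_step",
    "run_ciwp_pso",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightParams:
    """Shape parameters of the complementary inertia-weight pair.

    ``s_x`` scales the fitness coordinate (kept < 1 to avoid the logit
    singularity at x = ±0.5), ``s_y`` scales the output, ``m_x`` centres the
    sigmoid.
    """

    omega_min: float = 0.5
    omega_max: float = 0.9
    s_x: float = 0.96
    s_y: float = 7.8
    m_x: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.s_x < 1:
            raise ValueError("s_x must lie in (0, 1)")
        if self.s_y <= 0:
            raise ValueError("s_y must be positive")

    @classmethod
    def from_config(cls, config: SwarmConfig) -> "WeightParams":
        return cls(omega_min=config.omega_min, omega_max=config.omega_max)


@dataclass(frozen=True)
class LayerPartition:
    """Per-iteration pyramid split of particle indices by fitness."""

    elite: int
    middle: np.ndarray
    worst: np.ndarray

    @property
    def n_total(self) -> int:
        return 1 + self.middle.size + self.worst.size


def _round_half_up_int(x: float) -> int:
    return int(np.floor(x + 0.5))


def partition_layers(fitness: np.ndarray, rate: float) -> LayerPartition:
    """Sort by fitness (descending, ties to the lower index) and tier.

    The single best particle is the elite; the bottom
    ``round((1 - rate) * N)`` particles form the worst (opposition) tier —
    with ``rate = 0.9`` that is 10% of the swarm; the remainder is the
    middle tier.  A worst-tier size of 0 (``rate`` close to 1) disables ROL.
    """
    fitness = np.asarray(fitness)
    n = fitness.shape[0]
    if n < 3:
        raise ValueError("need at least 3 particles to form three layers")
    order = np.argsort(-fitness, kind="stable")
    n_worst = min(_round_half_up_int((1.0 - rate) * n), n - 2)
    elite = int(order[0])
    if n_worst > 0:
        worst = order[n - n_worst:]
        middle = order[1:n - n_worst]
    else:
        worst = order[:0]
        middle = order[1:]
    return LayerPartition(elite=elite, middle=middle, worst=worst)


def inverse_sigmoid(x: np.ndarray | float, params: WeightParams = WeightParams()) -> np.ndarray | float:
    """Scaled logit ``ln((s_x x + m_x)/(m_x - s_x x)) / s_y`` on [-0.5, 0.5].

    Odd, strictly increasing, and bounded (|S| < 0.5 for the default
    parameters).  Inputs outside [-0.5, 0.5] are clamped with a warning.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(np.abs(arr) > 0.5):
        if np.any(np.abs(arr) > 0.5 + 1e-9):  # beyond float jitter: worth flagging
            logger.warning("inverse_sigmoid input outside [-0.5, 0.5]; clamping")
        arr = np.clip(arr, -0.5, 0.5)
    p = params
    out = np.log((p.s_x * arr + p.m_x) / (p.m_x - p.s_x * arr)) / p.s_y
    return float(out) if np.isscalar(x) else out


def complementary_weights(
    f: np.ndarray | float,
    f_best: float,
    f_worst: float,
    params: WeightParams = WeightParams(),
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """The (omega, omega_reverse) pair for fitness ``f`` in [f_worst, f_best].

    The fitness coordinate is centred and scaled to ``[-0.5, 0.5]``; a
    degenerate swarm (``f_best == f_worst``) maps to ``x = 0`` so both
    weights sit at the midpoint.  Complementarity
    ``omega + omega_reverse == omega_min + omega_max`` holds by construction.
    """
    mid = (params.omega_min + params.omega_max) / 2.0
    span = params.omega_max - params.omega_min
    if f_best == f_worst:
        x = np.zeros_like(np.asarray(f, dtype=float))
    else:
        x = (np.asarray(f, dtype=float) - (f_best + f_worst) / 2.0) / (f_best - f_worst)
    s = inverse_sigmoid(x, params)
    omega = mid + span * s
    omega_rev = mid - span * s
    if np.isscalar(f):
        return float(omega), float(omega_rev)
    return omega, omega_rev


def rol_update(
    positions: np.ndarray,
    lower: float,
    upper: float,
    rng: np.random.Generator,
    per_dimension: bool = True,
) -> np.ndarray:
    """Random opposition learning: ``LB + UB - r * P``, clamped to the box.

    ``r`` is drawn per dimension by default (more diverse); set
    ``per_dimension=False`` for a single scalar draw per particle.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if per_dimension:
        r = rng.random(pos.shape)
    else:
        r = rng.random((pos.shape[0], 1))
    out = np.clip(lower + upper - r * pos, lower, upper)
    return out.reshape(np.shape(positions))


def ciwp_step(
    swarm: Swarm,
    partition: LayerPartition,
    gbest_position: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator,
    params: WeightParams | None = None,
) -> None:
    """One in-place CIWP update: elite frozen, middle weighted, worst mirrored.

    ``f_best``/``f_worst`` for the weight pair are the *current iteration's*
    swarm extremes, so the weights keep adapting as the swarm converges.
    Random draws are consumed in a fixed order (r1, r2, then ROL) so runs are
    reproducible and, with the worst tier disabled and
    ``omega_min == omega_max``, share the baseline's stream exactly.
    """
    if params is None:
        params = WeightParams.from_config(config)
    n, d = swarm.positions.shape
    r1 = rng.random((n, d))
    r2 = rng.random((n, d))
    f_best = float(swarm.fitness.max())
    f_worst = float(swarm.fitness.min())
    omega, omega_rev = complementary_weights(swarm.fitness, f_best, f_worst, params)
    attraction = config.c1 * r1 * (swarm.pbest_positions - swarm.positions) + (
        config.c2 * r2 * (gbest_position - swarm.positions)
    )
    new_v = np.clip(
        omega[:, None] * swarm.velocities + omega_rev[:, None] * attraction,
        -config.v_max,
        config.v_max,
    )
    new_x = np.clip(swarm.positions + new_v, config.lower, config.upper)
    mid = partition.middle
    swarm.velocities[mid] = new_v[mid]
    swarm.positions[mid] = new_x[mid]
    if partition.worst.size:
        # opposition tier: position replaced, velocity and pbest kept
        swarm.positions[partition.worst] = rol_update(
            swarm.positions[partition.worst],
            config.lower,
            config.upper,
            rng,
            per_dimension=config.rol_per_dimension,
        )


def run_ciwp_pso(
    objective: KapurObjective,
    config: SwarmConfig,
    rng: np.random.Generator | None = None,
) -> RunResult:
    """Maximise Kapur entropy with CIWP-PSO for ``T`` iterations.

    Loop: evaluate all particles (including ROL-moved ones) -> update
    personal/global bests -> partition into pyramid layers -> layered step.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = WeightParams.from_config(config)
    swarm = init_swarm(config, rng)
    convergence = np.empty(config.n_iterations)
    for t in range(config.n_iterations):
        _evaluate(swarm, objective)
        _update_pbest(swarm)
        g = swarm.gbest_index()
        convergence[t] = swarm.pbest_fitness[g]
        partition = partition_layers(swarm.fitness, config.rate)
        ciwp_step(swarm, partition, swarm.pbest_positions[g], config, rng, params)
    g = swarm.gbest_index()
    best_pos = swarm.pbest_positions[g].copy()
    return RunResult(
        best_position=best_pos,
        best_thresholds=decode_position(best_pos, objective.levels),
        best_fitness=float(swarm.pbest_fitness[g]),
        convergence=convergence,
    )
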