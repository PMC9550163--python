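"""Particle swarm optimization as a bounded black-box maximizer.

Standard global-best PSO: each particle i keeps a position x_i, velocity
v_i and personal best (pbest); the swarm shares a global best (gbest).
Velocities follow

    v_i(t+1) = w * v_i(t) + c1*u1*(pbest_i - x_i) + c2*u2*(gbest - x_i)
    x_i(t+1) = x_i(t) + v_i(t+1)

with fresh uniform u1, u2 per particle per iteration. Positions are clamped
to the search box (absorbing walls) and velocities to half the box width per
dimension. The implementation maximizes fitness throughout; a non-finite
fitness is recorded as -inf with a warning rather than crashing the swarm.

Used here to tune training hyperparameters (learning rate on a log scale,
batch size, weight decay, dropout) with validation accuracy as fitness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .backbone import BackboneSpec, TrainConfig, TrainingDivergence, train

__all__ = ["Particle", "SwarmState", "init_swarm", "step", "optimize", "tune_hyperparameters"]

logger = logging.getLogger(__name__)

DEFAULT_W = 0.7
DEFAULT_C1 = 1.5
DEFAULT_C2 = 1.5
DEFAULT_N_PARTICLES = 20
DEFAULT_N_ITERATIONS = 30


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest: np.ndarray
    gbest_fitness: float
    bounds: np.ndarray  # (d, 2)
    w: float = DEFAULT_W
    c1: float = DEFAULT_C1
    c2: float = DEFAULT_C2
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    iteration: int = 0


def _safe_fitness(fitness: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    val = float(fitness(x))
    if not np.isfinite(val):
        logger.warning("non-finite fitness at %s; recorded as -inf", x)
        return -np.inf
    return val


def init_swarm(
    fitness: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    n_particles: int,
    seed: int = 0,
    w: float = DEFAULT_W,
    c1: float = DEFAULT_C1,
    c2: float = DEFAULT_C2,
) -> SwarmState:
    """Positions uniform within bounds, velocities zero, pbest at the start."""
    box = np.asarray(bounds, dtype=np.float64)
    if box.ndim != 2 or box.shape[0] == 0 or box.shape[1] != 2:
        raise ValueError("bounds must be a nonempty list of (lo, hi) pairs")
    if np.any(box[:, 1] < box[:, 0]):
        raise ValueError("each bound must satisfy lo <= hi")
    if n_particles < 2:
        raise ValueError("need at least two particles")
    rng = np.random.default_rng(seed)
    d = box.shape[0]
    particles = []
    for _ in range(n_particles):
        x = box[:, 0] + rng.random(d) * (box[:, 1] - box[:, 0])
        f = _safe_fitness(fitness, x)
        particles.append(Particle(position=x, velocity=np.zeros(d), pbest=x.copy(), pbest_fitness=f))
    best = max(particles, key=lambda p: p.pbest_fitness)
    return SwarmState(
        particles=particles,
        gbest=best.pbest.copy(),
        gbest_fitness=best.pbest_fitness,
        bounds=box,
        w=w,
        c1=c1,
        c2=c2,
        rng=rng,
    )


def step(state: SwarmState, fitness: Callable[[np.ndarray], float]) -> SwarmState:
    """Advance the swarm one iteration in place and return it."""
    box = state.bounds
    vmax = 0.5 * (box[:, 1] - box[:, 0])
    for p in state.particles:
        u1 = state.rng.random(box.shape[0])
        u2 = state.rng.random(box.shape[0])
        p.velocity = (
            state.w * p.velocity
            + state.c1 * u1 * (p.pbest - p.position)
            + state.c2 * u2 * (state.gbest - p.position)
        )
        p.velocity = np.clip(p.velocity, -vmax, vmax)
        p.position = np.clip(p.position + p.velocity, box[:, 0], box[:, 1])
        f = _safe_fitness(fitness, p.position)
        if f > p.pbest_fitness:
            p.pbest = p.position.copy()
            p.pbest_fitness = f
            if f > state.gbest_fitness:
                state.gbest = p.position.copy()
                state.gbest_fitness = f
    state.iteration += 1
    return state


def optimize(
    fitness: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    n_particles: int = DEFAULT_N_PARTICLES,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = 0,
    w: float = DEFAULT_W,
    c1: float = DEFAULT_C1,
    c2: float = DEFAULT_C2,
) -> tuple[np.ndarray, float, list[float]]:
    """Run PSO for a fixed iteration budget.

    Returns the best position found, its fitness, and the per-iteration
    gbest-fitness trace (length ``n_iterations + 1`` including the
    initialisation point). Identical seeds give identical traces.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    state = init_swarm(fitness, bounds, n_particles, seed=seed, w=w, c1=c1, c2=c2)
    trace = [state.gbest_fitness]
    for _ in range(n_iterations):
        step(state, fitness)
        trace.append(state.gbest_fitness)
    return state.gbest.copy(), state.gbest_fitness, trace


# --------------------------------------------------- hyperparameter search

#: searchable TrainConfig dimensions; learning rate is searched in log10 space
TUNABLE_DIMENSIONS = ("log10_learning_rate", "batch_size", "weight_decay", "dropout")


def _decode(position: np.ndarray, names: Sequence[str], base: TrainConfig) -> TrainConfig:
    kwargs = {}
    for name, val in zip(names, position):
        if name == "log10_learning_rate":
            kwargs["learning_rate"] = float(10.0**val)
        elif name == "batch_size":
            kwargs["batch_size"] = max(1, int(round(val)))
        elif name == "weight_decay":
            kwargs["weight_decay"] = float(max(val, 0.0))
        elif name == "dropout":
            kwargs["dropout"] = float(min(max(val, 0.0), 0.99))
        else:
            raise ValueError(f"unknown search dimension {name!r}; expected {TUNABLE_DIMENSIONS}")
    return replace(base, **kwargs)


def tune_hyperparameters(
    spec: BackboneSpec,
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    search_space: Mapping[str, tuple[float, float]],
    n_particles: int = DEFAULT_N_PARTICLES,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = 0,
    base_config: TrainConfig | None = None,
) -> tuple[TrainConfig, float, list[float]]:
    """PSO search over training hyperparameters.

    ``search_space`` maps a subset of :data:`TUNABLE_DIMENSIONS` to (lo, hi)
    bounds; particle positions are decoded to a :class:`TrainConfig`
    (rounding integer dimensions) and scored by held-out validation
    accuracy. A training divergence scores -inf. Returns the decoded best
    config, its fitness and the gbest trace.
    """
    names = list(search_space)
    for n in names:
        if n not in TUNABLE_DIMENSIONS:
            raise ValueError(f"unknown search dimension {n!r}")
    base = base_config if base_config is not None else TrainConfig(seed=seed)

    def fitness(x: np.ndarray) -> float:
        cfg = _decode(x, names, base)
        try:
            return train(spec, images, labels, cfg).val_accuracy
        except TrainingDivergence:
            return -np.inf

    bounds = [search_space[n] for n in names]
    best_x, best_f, trace = optimize(
        fitness, bounds, n_particles=n_particles, n_iterations=n_iterations, seed=seed
    )
    return _decode(best_x, names, base), best_f, trace
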