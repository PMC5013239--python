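"""Search loops over fixed-length bitstrings: binary QPSO, sigmoid BPSO, GA.

All three maximise an arbitrary fitness function ``f(bits) -> value`` where
``value`` is either a plain number or any object exposing a numeric
``.score`` attribute (and optionally ``.accuracy``, as the SVM wrapper
objective does).  ``-inf`` is tolerated as the empty-subset sentinel; NaN
or ``+inf`` raise.

Contracts shared by the three loops:

* exactly ``swarm_size`` fitness evaluations at initialisation plus
  ``iterations * swarm_size`` afterwards;
* the global-best trajectory is monotone non-decreasing (GA guarantees this
  through elitism and best-ever bookkeeping);
* a run is fully determined by its seed: one ``numpy.random.Generator`` is
  created per run and every stochastic draw flows from it in a fixed order
  (initialisation first, then per iteration, per particle: crossover draw,
  jump draw, mutation draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .binary_core import (
    Bits,
    ParticleLayout,
    bits_to_string,
    get_local_attractor,
    get_mbest,
    jump_length,
    mutate_toward,
)

__all__ = [
    "BQPSOParams",
    "BPSOParams",
    "GAParams",
    "RunResult",
    "run_bqpso",
    "run_bpso",
    "run_ga",
]

FitnessFn = Callable[[Bits], object]


@dataclass(frozen=True)
class BQPSOParams:
    """Binary QPSO settings (defaults: swarm 20, 100 iterations, ce = 1)."""

    swarm_size: int = 20
    iterations: int = 100
    ce_coefficient: float = 1.0
    crossover_mode: str = "one-point"
    seed: int = 0


@dataclass(frozen=True)
class BPSOParams:
    """Sigmoid binary PSO settings (defaults: vmax 6, w 0.5, c1 = c2 = 2)."""

    swarm_size: int = 20
    iterations: int = 100
    v_max: float = 6.0
    inertia_w: float = 0.5
    c1: float = 2.0
    c2: float = 2.0
    seed: int = 0


@dataclass(frozen=True)
class GAParams:
    """Generational GA settings (defaults: crossover 0.9, mutation 0.04)."""

    population_size: int = 20
    iterations: int = 100
    p_crossover: float = 0.9
    p_mutation: float = 0.04
    selection: str = "roulette"
    elitism: int = 1
    seed: int = 0


@dataclass
class RunResult:
    """Outcome of one optimizer run."""

    best_position: str
    best_fitness: float
    best_accuracy: float | None
    selected_indices: list[int]
    fitness_trajectory: list[float]
    evaluations: int
    seed: int
    selected_genes: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "best_position": self.best_position,
            "best_fitness": self.best_fitness,
            "best_accuracy": self.best_accuracy,
            "selected_indices": list(self.selected_indices),
            "selected_genes": self.selected_genes,
            "fitness_trajectory": list(self.fitness_trajectory),
            "evaluations": self.evaluations,
            "seed": self.seed,
        }


def _score(value: object) -> float:
    s = float(getattr(value, "score", value))
    if math.isnan(s) or s == math.inf:
        raise ValueError(f"fitness produced a non-finite value: {s!r}")
    return s


def _accuracy(value: object) -> float | None:
    acc = getattr(value, "accuracy", None)
    return None if acc is None else float(acc)


def _result(
    best: Bits, best_value: object, trajectory: list[float], evals: int, seed: int
) -> RunResult:
    return RunResult(
        best_position=bits_to_string(best),
        best_fitness=_score(best_value),
        best_accuracy=_accuracy(best_value),
        selected_indices=[int(i) for i in np.flatnonzero(best)],
        fitness_trajectory=trajectory,
        evaluations=evals,
        seed=seed,
    )


def _init_swarm(
    fitness_fn: FitnessFn, length: int, size: int, rng: np.random.Generator
) -> tuple[list[Bits], list[object], list[float]]:
    """Bernoulli(0.5) initial positions with their fitness values."""
    positions = [rng.integers(0, 2, size=length, dtype=np.uint8) for _ in range(size)]
    values = [fitness_fn(p) for p in positions]
    return positions, values, [_score(v) for v in values]


def run_bqpso(
    fitness_fn: FitnessFn, layout: ParticleLayout, params: BQPSOParams
) -> RunResult:
    """Binary quantum-behaved PSO.

    Per iteration the mean best is recomputed from all personal bests; each
    particle then builds its local attractor by crossover of its personal
    best with the global best, draws a jump length against the mean best
    from its *current* position, and moves to a mutation of the attractor.
    Personal/global bests are updated under maximisation, with the incumbent
    retained on ties.
    """
    rng = np.random.default_rng(params.seed)
    l = layout.total_length
    positions, values, scores = _init_swarm(fitness_fn, l, params.swarm_size, rng)
    evals = params.swarm_size

    pbest = [p.copy() for p in positions]
    pbest_val = list(values)
    pbest_score = list(scores)
    g = int(np.argmax(pbest_score))
    gbest, gbest_val, gbest_score = pbest[g].copy(), pbest_val[g], pbest_score[g]
    trajectory = [gbest_score]

    for _ in range(params.iterations):
        mbest = get_mbest(pbest, rng)
        for i in range(params.swarm_size):
            attractor = get_local_attractor(
                pbest[i], gbest, rng, mode=params.crossover_mode
            )
            draw = jump_length(positions[i], mbest, params.ce_coefficient, rng)
            new_pos = mutate_toward(attractor, draw, rng)
            value = fitness_fn(new_pos)
            evals += 1
            s = _score(value)
            positions[i] = new_pos
            if s > pbest_score[i]:
                pbest[i], pbest_val[i], pbest_score[i] = new_pos.copy(), value, s
                if s > gbest_score:
                    gbest, gbest_val, gbest_score = new_pos.copy(), value, s
        trajectory.append(gbest_score)

    return _result(gbest, gbest_val, trajectory, evals, params.seed)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def _bpso_velocity(
    v: np.ndarray,
    x: Bits,
    pbest: Bits,
    gbest: Bits,
    params: BPSOParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inertia + cognitive + social update, clamped to [-v_max, v_max]."""
    r1 = rng.random(v.shape[0])
    r2 = rng.random(v.shape[0])
    new_v = (
        params.inertia_w * v
        + params.c1 * r1 * (pbest.astype(float) - x.astype(float))
        + params.c2 * r2 * (gbest.astype(float) - x.astype(float))
    )
    return np.clip(new_v, -params.v_max, params.v_max)


def run_bpso(
    fitness_fn: FitnessFn, layout: ParticleLayout, params: BPSOParams
) -> RunResult:
    """Canonical sigmoid binary PSO: real velocities, bit j set to 1 with
    probability sigmoid(v_j)."""
    rng = np.random.default_rng(params.seed)
    l = layout.total_length
    positions, values, scores = _init_swarm(fitness_fn, l, params.swarm_size, rng)
    velocities = [rng.uniform(-params.v_max, params.v_max, size=l) for _ in positions]
    evals = params.swarm_size

    pbest = [p.copy() for p in positions]
    pbest_val = list(values)
    pbest_score = list(scores)
    g = int(np.argmax(pbest_score))
    gbest, gbest_val, gbest_score = pbest[g].copy(), pbest_val[g], pbest_score[g]
    trajectory = [gbest_score]

    for _ in range(params.iterations):
        for i in range(params.swarm_size):
            velocities[i] = _bpso_velocity(
                velocities[i], positions[i], pbest[i], gbest, params, rng
            )
            new_pos = (rng.random(l) < _sigmoid(velocities[i])).astype(np.uint8)
            value = fitness_fn(new_pos)
            evals += 1
            s = _score(value)
            positions[i] = new_pos
            if s > pbest_score[i]:
                pbest[i], pbest_val[i], pbest_score[i] = new_pos.copy(), value, s
                if s > gbest_score:
                    gbest, gbest_val, gbest_score = new_pos.copy(), value, s
        trajectory.append(gbest_score)

    return _result(gbest, gbest_val, trajectory, evals, params.seed)


def _roulette_pick(
    scores: Sequence[float], rng: np.random.Generator
) -> int:
    """Fitness-proportional (roulette) selection on raw scores.

    Raw scores serve as weights when all are non-negative; if negatives are
    present the scores are shifted so the minimum maps to zero (sentinel
    ``-inf`` scores get zero weight).  When every weight is zero — an
    all-equal non-positive population, or all sentinels — selection falls
    back to uniform.
    """
    arr = np.asarray(scores, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        return int(rng.integers(0, len(arr)))
    low = arr[finite].min()
    weights = np.where(finite, arr - low if low < 0 else arr, 0.0)
    total = weights.sum()
    if total <= 0.0:
        return int(rng.integers(0, len(arr)))
    return int(np.searchsorted(np.cumsum(weights), rng.random() * total, side="right"))


def run_ga(
    fitness_fn: FitnessFn, layout: ParticleLayout, params: GAParams
) -> RunResult:
    """Generational GA: roulette (or tournament) selection, one-point
    crossover, independent per-bit mutation, elitism.

    The whole population, elites included, is (re)evaluated each generation
    so the evaluation budget matches the swarm loops exactly; the objective
    is deterministic so elitism still guarantees a monotone trajectory.
    """
    rng = np.random.default_rng(params.seed)
    l = layout.total_length
    pop, values, scores = _init_swarm(fitness_fn, l, params.population_size, rng)
    evals = params.population_size

    order = np.argsort(scores)[::-1]
    best, best_val, best_score = (
        pop[order[0]].copy(),
        values[order[0]],
        scores[order[0]],
    )
    trajectory = [best_score]

    def select_parent() -> Bits:
        if params.selection == "roulette":
            return pop[_roulette_pick(scores, rng)]
        if params.selection == "tournament":
            i, j = rng.integers(0, params.population_size, size=2)
            return pop[i] if scores[i] >= scores[j] else pop[j]
        raise ValueError(f"unknown selection scheme: {params.selection!r}")

    for _ in range(params.iterations):
        elites = [pop[i].copy() for i in np.argsort(scores)[::-1][: params.elitism]]
        children: list[Bits] = []
        while len(children) < params.population_size - params.elitism:
            p1, p2 = select_parent(), select_parent()
            if l > 1 and rng.random() < params.p_crossover:
                cut = int(rng.integers(1, l))
                c1 = np.concatenate([p1[:cut], p2[cut:]])
                c2 = np.concatenate([p2[:cut], p1[cut:]])
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                if len(children) >= params.population_size - params.elitism:
                    break
                flips = rng.random(l) < params.p_mutation
                child[flips] ^= 1
                children.append(child)
        pop = elites + children
        values = [fitness_fn(p) for p in pop]
        evals += params.population_size
        scores = [_score(v) for v in values]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best, best_val, best_score = (
                pop[gen_best].copy(),
                values[gen_best],
                scores[gen_best],
            )
        trajectory.append(best_score)

    return _result(best, best_val, trajectory, evals, params.seed)
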