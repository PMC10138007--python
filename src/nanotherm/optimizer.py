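"""Differential evolution (best/1/bin) over injection coordinates.

The decision vector concatenates the Np injection points, giving
Nparam = 3·Np coordinates bounded by the domain cube. The population holds
``pop_multiplier × Nparam`` individuals (35 × Nparam by default). Each
generation applies, per target individual,

  mutation   V = X_best + F·(X_a − X_b)   with a, b distinct, ≠ best, ≠ target
  crossover  binomial mixing of V with the target at rate C, with one
             uniformly chosen coordinate always taken from the mutant
  selection  the trial replaces the target iff its objective is ≤

and stops when the population objectives satisfy
``std ≤ atol + tol·|mean|`` or after ``max_generations`` (the run is then
flagged unconverged rather than raising). Objective evaluations are cached:
the objective is a pure function of the coordinates and a full bioheat
simulation each, so identical individuals are never re-simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

log = logging.getLogger(__name__)

from .damage import evaluate_injections
from .sar import InjectionSet
from .scenario import Scenario

__all__ = [
    "DESettings",
    "Population",
    "OptimizationResult",
    "init_population",
    "mutate_best1",
    "crossover_bin",
    "select",
    "converged",
    "differential_evolution",
    "optimize",
]


@dataclass
class DESettings:
    """Differential-evolution hyperparameters.

    F may be a single mutation factor or a (low, high) dither interval
    resampled uniformly each generation. ``bounds`` is an (Nparam, 2) array;
    when ``None``, ``optimize`` uses the domain cube per coordinate.
    ``force_crossover`` keeps the standard guarantee that at least one
    coordinate comes from the mutant; disable for the literal textbook rule.
    """

    pop_multiplier: int = 35
    F: "float | tuple[float, float]" = (0.5, 1.0)
    C: float = 0.7
    atol: float = 0.0
    tol: float = 0.01
    max_generations: int = 10_000
    seed: int | None = None
    bounds: np.ndarray | None = None
    force_crossover: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.C <= 1.0:
            raise ValueError(f"C must lie in [0, 1], got {self.C}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.pop_multiplier < 1:
            raise ValueError("pop_multiplier must be >= 1")


@dataclass
class Population:
    """DE population: (pop_size, Nparam) individuals plus their objectives."""

    individuals: np.ndarray
    objectives: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.individuals.shape[0]

    @property
    def best_index(self) -> int:
        if self.objectives is None:
            raise ValueError("population objectives not evaluated yet")
        return int(np.argmin(self.objectives))

    @property
    def best(self) -> np.ndarray:
        return self.individuals[self.best_index]


@dataclass
class OptimizationResult:
    """Outcome of one DE run."""

    best_points: InjectionSet
    best_objective: float
    generations: int
    converged: bool
    history: list[tuple[float, float, float]]  # per-generation (best, mean, std)
    seed: int | None
    n_evaluations: int = 0

    @property
    def best_vector(self) -> np.ndarray:
        pts = self.best_points
        return pts.points.ravel() if isinstance(pts, InjectionSet) else np.asarray(pts).ravel()


def init_population(bounds: np.ndarray, pop_size: int, seed) -> Population:
    """Uniform random population within per-coordinate bounds.

    ``seed`` may be an int or a ``numpy.random.Generator``. best/1 mutation
    needs the best, two distinct others and the target, hence pop_size ≥ 4.
    """
    bounds = np.asarray(bounds, dtype=float)
    if pop_size < 4:
        raise ValueError(f"pop_size must be >= 4 for best/1/bin, got {pop_size}")
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must have shape (Nparam, 2)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = bounds[:, 0], bounds[:, 1]
    ind = rng.uniform(lo, hi, size=(pop_size, bounds.shape[0]))
    return Population(individuals=ind)


def mutate_best1(population: Population, a_idx: int, b_idx: int, F: float) -> np.ndarray:
    """best/1 mutant V = X_best + F·(X_a − X_b)."""
    best = population.best_index
    if a_idx == b_idx or best in (a_idx, b_idx):
        raise ValueError(
            f"mutation indices must be distinct from each other and from the "
            f"best individual (best={best}, a={a_idx}, b={b_idx})"
        )
    x = population.individuals
    return x[best] + F * (x[a_idx] - x[b_idx])


def crossover_bin(
    mutant: np.ndarray,
    target: np.ndarray,
    C: float,
    rng: np.random.Generator,
    force_index: bool = True,
) -> np.ndarray:
    """Binomial crossover: each coordinate comes from the mutant with
    probability C (r_i ≤ C), else from the target.

    With ``force_index`` (the standard convention), one uniformly chosen
    coordinate is always taken from the mutant so the trial never degenerates
    to the target even at C = 0.
    """
    mutant = np.asarray(mutant, float)
    target = np.asarray(target, float)
    if mutant.shape != target.shape:
        raise ValueError("mutant and target must have the same shape")
    take = rng.uniform(size=mutant.shape) <= C
    if force_index:
        take[rng.integers(mutant.size)] = True
    return np.where(take, mutant, target)


def select(trial, target, obj_trial: float, obj_target: float):
    """Greedy selection: the trial survives iff its objective is ≤ the target's."""
    return (trial, obj_trial) if obj_trial <= obj_target else (target, obj_target)


def converged(objectives: np.ndarray, atol: float, tol: float) -> bool:
    """Stopping rule: population std ≤ atol + tol·|population mean|."""
    objectives = np.asarray(objectives, dtype=float)
    if objectives.size == 0:
        raise ValueError("objective vector is empty")
    return bool(np.std(objectives) <= atol + tol * abs(np.mean(objectives)))


def differential_evolution(
    func: Callable[[np.ndarray], float],
    bounds: "np.ndarray | Sequence[tuple[float, float]]",
    settings: DESettings | None = None,
    pop_size: int | None = None,
) -> OptimizationResult:
    """Minimize ``func`` over a box with best/1/bin differential evolution.

    Generic core used by :func:`optimize`; ``func`` maps an (Nparam,) vector
    to a scalar. Out-of-bounds trial coordinates are clipped to the box.
    Identical vectors reuse cached objective values.
    """
    settings = settings or DESettings()
    bounds = np.asarray(bounds, dtype=float)
    nparam = bounds.shape[0]
    if pop_size is None:
        pop_size = settings.pop_multiplier * nparam
    rng = np.random.default_rng(settings.seed)
    lo, hi = bounds[:, 0], bounds[:, 1]

    cache: dict[bytes, float] = {}
    n_eval = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_eval
        key = x.tobytes()
        if key not in cache:
            cache[key] = float(func(x))
            n_eval += 1
        return cache[key]

    pop = init_population(bounds, pop_size, rng)
    pop.objectives = np.array([evaluate(x) for x in pop.individuals])

    history: list[tuple[float, float, float]] = []
    is_converged = False
    generation = 0

    f_spec = settings.F
    dither = isinstance(f_spec, (tuple, list))

    for generation in range(1, settings.max_generations + 1):
        F = rng.uniform(*f_spec) if dither else float(f_spec)
        best = pop.best_index
        new_ind = np.empty_like(pop.individuals)
        new_obj = np.empty_like(pop.objectives)
        for r in range(pop.size):
            candidates = [i for i in range(pop.size) if i != r and i != best]
            a_idx, b_idx = rng.choice(candidates, size=2, replace=False)
            mutant = mutate_best1(pop, int(a_idx), int(b_idx), F)
            trial = crossover_bin(
                mutant, pop.individuals[r], settings.C, rng, settings.force_crossover
            )
            np.clip(trial, lo, hi, out=trial)
            survivor, obj = select(
                trial, pop.individuals[r], evaluate(trial), pop.objectives[r]
            )
            new_ind[r] = survivor
            new_obj[r] = obj
        pop = Population(new_ind, new_obj)
        stats = (float(new_obj.min()), float(new_obj.mean()), float(np.std(new_obj)))
        history.append(stats)
        log.info(
            "generation %d: best=%.6f mean=%.6f std=%.6f", generation, *stats
        )
        if converged(new_obj, settings.atol, settings.tol):
            is_converged = True
            break

    best_x = pop.best.copy()
    # a decision vector that is not a list of 3-D points is kept as-is
    best_points = InjectionSet(best_x.reshape(-1, 3)) if nparam % 3 == 0 else best_x
    return OptimizationResult(
        best_points=best_points,
        best_objective=float(pop.objectives[pop.best_index]),
        generations=generation,
        converged=is_converged,
        history=history,
        seed=settings.seed,
        n_evaluations=n_eval,
    )


def optimize(
    scenario: Scenario,
    Np: int | None = None,
    settings: DESettings | None = None,
    **simulate_kwargs,
) -> OptimizationResult:
    """Search for the Np injection points minimizing the damage objective.

    Bounds default to the full domain cube per coordinate. Keyword arguments
    (``ht``, ``t_end``, ``engine``, ...) are forwarded to the bioheat
    simulation of every objective evaluation. An unconverged run (stopping
    rule unmet after ``max_generations``) is returned flagged, not raised.
    """
    settings = settings or DESettings()
    Np = scenario.treatment.Np if Np is None else int(Np)
    if Np < 1:
        raise ValueError("Np must be >= 1")
    nparam = 3 * Np
    if settings.bounds is not None:
        bounds = np.asarray(settings.bounds, dtype=float)
        if bounds.shape != (nparam, 2):
            raise ValueError(f"bounds must have shape ({nparam}, 2)")
    else:
        bounds = np.tile([0.0, scenario.domain.side_length], (nparam, 1))

    def func(x: np.ndarray) -> float:
        report = evaluate_injections(scenario, x.reshape(Np, 3), **simulate_kwargs)
        return report.objective

    return differential_evolution(func, bounds, settings)
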