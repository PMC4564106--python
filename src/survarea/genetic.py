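"""Steady-state genetic training of one membership classifier.

The optimizer maintains a fixed-size population of genomes.  Each cycle:
two parents are drawn by binary tournament, cloned, recombined by
two-point crossover with probability P_C, Gaussian-mutated per weight
with probability P_M, evaluated, and re-inserted alongside the parents;
the two worst individuals are then discarded to restore the population
size.  A generation has elapsed once ``population_size`` children have
been born.  The result of a run is the single best genome ever evaluated,
which need not survive in the final population.

Defaults follow the tuned values that work across tabular clinical
datasets: population 200, P_C = 0.75, P_M = 0.5, mutation sd 1.5,
1000 generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ann import Genome, MLPArchitecture, raw_output
from .data import SurvivalDataset
from .objective import AreaFitness, FitnessSpec

__all__ = [
    "GAConfig",
    "GAState",
    "initialize",
    "tournament_select",
    "crossover_two_point",
    "mutate_gaussian",
    "insert_and_cull",
    "train",
]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    crossover_prob: float = 0.75
    mutation_prob: float = 0.5
    mutation_std: float = 1.5
    generations: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mutation_std <= 0:
            raise ValueError("mutation_std must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class GAState:
    """Population with bookkeeping for steady-state replacement.

    ``birth_order`` breaks fitness ties during culling: among equally
    unfit individuals the oldest is discarded first, which keeps runs
    deterministic under a fixed seed.
    """

    population: list[Genome]
    birth_order: list[int]
    best_ever: Genome
    children_born: int = 0
    _next_birth: int = field(default=0)

    @property
    def size(self) -> int:
        return len(self.population)

    def register_birth(self) -> int:
        b = self._next_birth
        self._next_birth += 1
        return b


def initialize(
    arch: MLPArchitecture,
    config: GAConfig,
    evaluate,
    rng: np.random.Generator,
) -> GAState:
    """Population of random genomes, standard-normal weights, all scored."""
    population = []
    for _ in range(config.population_size):
        g = Genome(rng.standard_normal(arch.genome_length))
        g.fitness = evaluate(g)
        population.append(g)
    best = max(population, key=lambda g: g.fitness).copy()
    state = GAState(
        population,
        birth_order=list(range(config.population_size)),
        best_ever=best,
    )
    state._next_birth = config.population_size
    return state


def tournament_select(state: GAState, rng: np.random.Generator) -> Genome:
    """Binary tournament: two uniform picks (duplicates allowed), fitter wins."""
    i, j = rng.integers(0, state.size, size=2)
    a, b = state.population[i], state.population[j]
    return a if a.fitness >= b.fitness else b


def crossover_two_point(
    parent_a: Genome,
    parent_b: Genome,
    p_crossover: float,
    rng: np.random.Generator,
) -> tuple[Genome, Genome]:
    """Clone both parents; with probability P_C swap the segment between
    two pivots drawn uniformly from the L+1 boundary positions (equal
    pivots leave the clones untouched)."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal genome length")
    child_a = Genome(parent_a.weights.copy())
    child_b = Genome(parent_b.weights.copy())
    if rng.random() < p_crossover:
        lo, hi = np.sort(rng.integers(0, len(parent_a) + 1, size=2))
        seg = child_a.weights[lo:hi].copy()
        child_a.weights[lo:hi] = child_b.weights[lo:hi]
        child_b.weights[lo:hi] = seg
    return child_a, child_b


def mutate_gaussian(
    genome: Genome,
    p_mutation: float,
    mutation_std: float,
    rng: np.random.Generator,
) -> Genome:
    """Each weight independently gets +N(0, mutation_std) with prob P_M;
    untouched weights stay bit-identical."""
    out = Genome(genome.weights.copy())
    hit = rng.random(len(out)) < p_mutation
    if hit.any():
        out.weights[hit] += rng.normal(0.0, mutation_std, size=int(hit.sum()))
    return out


def insert_and_cull(
    state: GAState, parents: tuple[Genome, Genome], children: tuple[Genome, Genome]
) -> GAState:
    """Add both children (parents stay), drop the two worst, update best."""
    for child in children:
        if child.fitness is None:
            raise ValueError("children must be evaluated before insertion")
        state.population.append(child)
        state.birth_order.append(state.register_birth())
        state.children_born += 1
        if child.fitness > state.best_ever.fitness:
            state.best_ever = child.copy()
    for _ in range(2):
        worst = min(
            range(len(state.population)),
            key=lambda k: (state.population[k].fitness, state.birth_order[k]),
        )
        state.population.pop(worst)
        state.birth_order.pop(worst)
    return state


def train(
    data: SurvivalDataset,
    spec: FitnessSpec,
    arch: MLPArchitecture,
    config: GAConfig,
    rng: np.random.Generator | None = None,
    trace: list | None = None,
) -> Genome:
    """Evolve one membership classifier on (already preprocessed) data.

    Parameters
    ----------
    trace : list, optional
        If given, receives one dict per generation with keys
        ``generation, best_fitness, mean_fitness, best_group_size`` —
        the run log (writable to CSV via pandas).

    Returns
    -------
    Genome
        The best genome observed at any point during the run.
    """
    if spec.m >= len(data):
        raise ValueError(
            f"minimum group size m={spec.m} must be smaller than the "
            f"dataset ({len(data)} subjects)"
        )
    if data.covariates is None:
        raise ValueError("training requires covariates")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = data.covariates.to_numpy(dtype=float)
    if X.shape[1] != arch.n_inputs:
        raise ValueError(
            f"architecture expects {arch.n_inputs} inputs, data has "
            f"{X.shape[1]} covariates"
        )
    evaluator = AreaFitness(data.times, data.events, spec)

    def evaluate(genome: Genome) -> float:
        return evaluator(raw_output(genome, arch, X) > 0.0)

    state = initialize(arch, config, evaluate, rng)
    cycles_per_generation = (config.population_size + 1) // 2

    def log_generation(gen: int) -> None:
        if trace is None:
            return
        fits = np.array([g.fitness for g in state.population])
        best = state.best_ever
        trace.append(
            {
                "generation": gen,
                "best_fitness": float(best.fitness),
                "mean_fitness": float(fits.mean()),
                "best_group_size": int(
                    (raw_output(best, arch, X) > 0.0).sum()
                ),
            }
        )

    log_generation(0)
    for gen in range(1, config.generations + 1):
        for _ in range(cycles_per_generation):
            pa = tournament_select(state, rng)
            pb = tournament_select(state, rng)
            ca, cb = crossover_two_point(pa, pb, config.crossover_prob, rng)
            ca = mutate_gaussian(ca, config.mutation_prob, config.mutation_std, rng)
            cb = mutate_gaussian(cb, config.mutation_prob, config.mutation_std, rng)
            ca.fitness = evaluate(ca)
            cb.fitness = evaluate(cb)
            insert_and_cull(state, (pa, pb), (ca, cb))
        log_generation(gen)

    if state.best_ever.fitness == 0.0:
        warnings.warn(
            "every candidate group violated the minimum size constraint "
            f"(m={spec.m}); the returned classifier is degenerate",
            stacklevel=2,
        )
    return state.best_ever
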