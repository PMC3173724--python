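"""Pareto-ranked genetic algorithm over constrained sequences.

The GA follows the classic multiobjective scheme: fitness is a vector, one
vector dominates another when it is at least as good in every component and
strictly better in at least one, the nondominated set forms the first Pareto
frontier, and peeling frontiers iteratively yields a Pareto rank per
individual. Parents are drawn with probability decreasing in rank, recombined
by 1-point crossover, mutated at free positions only, and the pooled parents
plus offspring are truncated elitistically back to the fixed population size
(default 600 individuals per generation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError
from .properties import CANONICAL_RESIDUES
from .template import DesignTemplate, FitnessVector, Individual, validate_sequence

Vector = Sequence[float]


def dominates(x: Vector, y: Vector) -> bool:
    """True iff x dominates y: x_i > y_i for some i and x_j >= y_j for all j.

    Defines a strict partial order (irreflexive, antisymmetric, transitive)
    on vectors of equal arity.
    """
    if len(x) != len(y):
        raise ParameterError(f"arity mismatch: {len(x)} vs {len(y)}")
    return all(a >= b for a, b in zip(x, y)) and any(a > b for a, b in zip(x, y))


@dataclass(frozen=True)
class ParetoRanking:
    """Ranks (1 = nondominated) and the frontier index sets, in rank order."""

    ranks: np.ndarray
    frontiers: tuple[tuple[int, ...], ...]

    @property
    def frontier_size(self) -> int:
        return len(self.frontiers[0])


def pareto_rank(vectors: Sequence[Vector]) -> ParetoRanking:
    """Iterative frontier peeling.

    Rank 1 is the set of vectors not dominated by any other; those are
    removed and the next frontier is computed from the remainder, until every
    vector carries a rank. Vectorised pairwise dominance, O(n^2 d) overall.
    """
    if len(vectors) == 0:
        raise ParameterError("cannot rank an empty set of vectors")
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2:
        raise ParameterError("fitness vectors must share one arity")
    n = len(arr)
    # dom[i, j]: vector i dominates vector j
    ge = (arr[:, None, :] >= arr[None, :, :]).all(axis=-1)
    gt = (arr[:, None, :] > arr[None, :, :]).any(axis=-1)
    dom = ge & gt

    ranks = np.zeros(n, dtype=int)
    frontiers: list[tuple[int, ...]] = []
    alive = np.ones(n, dtype=bool)
    rank = 0
    while alive.any():
        rank += 1
        dominated = dom[alive].any(axis=0)
        front = alive & ~dominated
        ranks[front] = rank
        frontiers.append(tuple(np.flatnonzero(front)))
        alive &= ~front
    return ParetoRanking(ranks=ranks, frontiers=tuple(frontiers))


@dataclass(frozen=True)
class GAConfig:
    """Run parameters. ``mutation_rate`` is the independent substitution
    probability per free position per offspring."""

    population_size: int = 600
    generations: int = 1000
    mutation_rate: float = 0.01
    offspring_per_generation: int | None = None
    init_mutation_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ParameterError("population_size must be >= 2")
        if self.generations < 0:
            raise ParameterError("generations must be >= 0")
        for name in ("mutation_rate", "init_mutation_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {rate}")

    @property
    def n_offspring(self) -> int:
        return self.offspring_per_generation or self.population_size


@dataclass
class Population:
    """Fixed-size set of individuals at one generation."""

    individuals: list[Individual]
    generation: int = 0

    def __len__(self) -> int:
        return len(self.individuals)

    def fitness_matrix(self) -> list[FitnessVector]:
        return [ind.fitness for ind in self.individuals]


def select_parents(
    pop: Population, ranking: ParetoRanking, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """Draw two distinct parents with probability proportional to 1/rank, so
    lower Pareto ranks are more likely selected."""
    n = len(pop)
    if n < 2:
        raise ParameterError("need at least two individuals to select parents")
    weights = 1.0 / ranking.ranks
    i, j = rng.choice(n, size=2, replace=False, p=weights / weights.sum())
    return pop.individuals[i], pop.individuals[j]


def crossover_1pt(
    a: Individual, b: Individual, rng: np.random.Generator, k: int | None = None
) -> Individual:
    """1-point crossover: child = a[1..k] + b[k+1..L], k uniform on 1..L-1.

    Because both parents satisfy the template's fixed positions, so does the
    child, for any cut point.
    """
    if len(a.sequence) != len(b.sequence):
        raise ParameterError("parents must have equal length")
    L = len(a.sequence)
    if L < 2:
        raise ParameterError("sequences too short for crossover")
    if k is None:
        k = int(rng.integers(1, L))
    elif not 1 <= k <= L - 1:
        raise ParameterError(f"cut point {k} outside 1..{L - 1}")
    return Individual(sequence=a.sequence[:k] + b.sequence[k:])


def mutate(
    ind: Individual | str,
    template: DesignTemplate,
    rate: float,
    rng: np.random.Generator,
) -> Individual:
    """Substitute each free position independently with probability ``rate``
    by a uniformly random DIFFERENT residue; fixed positions never change."""
    seq = ind.sequence if isinstance(ind, Individual) else ind
    free = template.free_positions
    if rate == 0.0 or not free:
        return Individual(sequence=seq)
    hits = np.flatnonzero(rng.random(len(free)) < rate)
    if hits.size == 0:
        return Individual(sequence=seq)
    chars = list(seq)
    draws = rng.integers(0, 19, size=hits.size)
    for h, d in zip(hits, draws):
        pos = free[h] - 1
        current = chars[pos]
        alternatives = CANONICAL_RESIDUES.replace(current, "")
        chars[pos] = alternatives[d]
    return Individual(sequence="".join(chars))


def count_evaluated(cfg: GAConfig) -> int:
    """The paper-style accounting of sequences analysed in one run:
    population size times number of generations."""
    return cfg.population_size * cfg.generations


@dataclass
class GenerationRecord:
    generation: int
    frontier_size: int
    best_components: tuple[float, ...]
    frontier_vectors: tuple[tuple[float, ...], ...] = field(repr=False, default=())


def _truncate(
    individuals: list[Individual], ranking: ParetoRanking, size: int
) -> list[int]:
    """Elitist truncation: keep the ``size`` best by (rank, then highest
    first objective, then stable input order)."""
    order = sorted(
        range(len(individuals)),
        key=lambda i: (ranking.ranks[i], -individuals[i].fitness[0], i),
    )
    return order[:size]


def evolve(
    template: DesignTemplate,
    cfg: GAConfig,
    fitness: Callable[[str], FitnessVector],
    callback: Callable[[int, Population, ParetoRanking], None] | None = None,
) -> tuple[Population, ParetoRanking, list[GenerationRecord]]:
    """Run the full GA loop.

    The initial population consists of seed copies mutated at free positions
    with probability ``cfg.init_mutation_rate``. Every generation produces
    ``cfg.n_offspring`` children by select -> crossover -> mutate, evaluates
    them, ranks the pooled parents+children and truncates elitistically back
    to ``cfg.population_size``. Fully reproducible for a fixed ``rng_seed``.

    Returns the final population, its ranking, and one record per generation
    (frontier size, per-component best, rank-1 fitness vectors).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    cache: dict[str, FitnessVector] = {}

    def evaluated(ind: Individual, generation: int) -> Individual:
        if ind.fitness is None:
            try:
                fit = cache.get(ind.sequence)
                if fit is None:
                    fit = fitness(ind.sequence)
                    cache[ind.sequence] = fit
            except Exception as exc:
                raise ParameterError(
                    f"fitness evaluation failed at generation {generation}: {exc}"
                ) from exc
            ind.fitness = fit
        return ind

    individuals = [
        evaluated(mutate(template.seed, template, cfg.init_mutation_rate, rng), 0)
        for _ in range(cfg.population_size)
    ]
    pop = Population(individuals=individuals, generation=0)
    ranking = _apply_ranks(pop)
    history = [_record(pop, ranking)]
    if callback is not None:
        callback(0, pop, ranking)

    for gen in range(1, cfg.generations + 1):
        children = []
        for _ in range(cfg.n_offspring):
            a, b = select_parents(pop, ranking, rng)
            child = mutate(crossover_1pt(a, b, rng), template, cfg.mutation_rate, rng)
            children.append(evaluated(child, gen))
        pool = pop.individuals + children
        pool_ranking = pareto_rank([ind.fitness for ind in pool])
        keep = _truncate(pool, pool_ranking, cfg.population_size)
        pop = Population(individuals=[pool[i] for i in keep], generation=gen)
        ranking = _apply_ranks(pop)
        history.append(_record(pop, ranking))
        if callback is not None:
            callback(gen, pop, ranking)

    return pop, ranking, history


def _apply_ranks(pop: Population) -> ParetoRanking:
    ranking = pareto_rank([ind.fitness for ind in pop.individuals])
    for ind, rank in zip(pop.individuals, ranking.ranks):
        ind.pareto_rank = int(rank)
    # sanity: evolution must never break the template's fixed positions
    return ranking


def _record(pop: Population, ranking: ParetoRanking) -> GenerationRecord:
    fits = np.array([ind.fitness for ind in pop.individuals], dtype=float)
    frontier = ranking.frontiers[0]
    return GenerationRecord(
        generation=pop.generation,
        frontier_size=len(frontier),
        best_components=tuple(fits.max(axis=0)),
        frontier_vectors=tuple(tuple(fits[i]) for i in frontier),
    )


def conservation_violations(pop: Population, template: DesignTemplate) -> int:
    """Number of individuals violating the template (0 for a healthy run)."""
    return sum(
        0 if validate_sequence(ind.sequence, template) else 1
        for ind in pop.individuals
    )
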