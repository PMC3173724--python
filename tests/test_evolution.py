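import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from helixgraft import (
    GAConfig,
    Individual,
    Population,
    count_evaluated,
    crossover_1pt,
    dominates,
    evolve,
    mutate,
    pareto_rank,
    select_parents,
    validate_sequence,
)
from helixgraft.errors import ParameterError
from helixgraft.evolution import conservation_violations
from oracles import oracle_dominates, oracle_pareto_ranks

vectors3 = st.tuples(
    st.integers(0, 4), st.integers(0, 4), st.integers(0, 4)
)


class TestDominates:
    def test_worked_example(self):
        x, y, z = (3, 1, 2), (3, 1, 1), (4, 0, 2)
        assert dominates(x, y)  # x_3 > y_3, others equal
        assert not dominates(z, x) and not dominates(x, z)
        assert not dominates(z, y) and not dominates(y, z)

    def test_irreflexive(self):
        assert not dominates((3, 1, 2), (3, 1, 2))

    def test_arity_mismatch(self):
        with pytest.raises(ParameterError):
            dominates((1, 2), (1, 2, 3))

    @given(vectors3, vectors3, vectors3)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_strict_partial_order(self, x, y, z):
        assert not dominates(x, x)
        if dominates(x, y):
            assert not dominates(y, x)
        if dominates(x, y) and dominates(y, z):
            assert dominates(x, z)

    @given(vectors3, vectors3)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_oracle(self, x, y):
        assert dominates(x, y) == oracle_dominates(x, y)


class TestParetoRank:
    def test_singleton(self):
        r = pareto_rank([(1.0, 2.0)])
        assert list(r.ranks) == [1]
        assert r.frontiers == ((0,),)

    def test_worked_example_frontiers(self):
        vecs = [(3, 1, 2), (3, 1, 1), (4, 0, 2)]
        r = pareto_rank(vecs)
        assert set(r.frontiers[0]) == {0, 2}
        assert set(r.frontiers[1]) == {1}
        assert list(r.ranks) == [1, 2, 1]

    def test_frontiers_partition_population(self, rng):
        vecs = rng.normal(size=(40, 3))
        r = pareto_rank(vecs)
        flat = sorted(i for front in r.frontiers for i in front)
        assert flat == list(range(40))

    def test_random_sets_match_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 50))
            vecs = [tuple(v) for v in rng.normal(size=(n, 3))]
            assert list(pareto_rank(vecs).ranks) == oracle_pareto_ranks(vecs)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            pareto_rank([])


def _toy_population(fits):
    pop = Population(
        individuals=[Individual("AAAA", fitness=f) for f in fits]
    )
    return pop, pareto_rank(fits)


class TestSelectParents:
    def test_uniform_when_all_rank_one(self, rng):
        fits = [(1.0, float(i), float(-i)) for i in range(5)]  # all nondominated
        pop, ranking = _toy_population(fits)
        assert set(ranking.ranks) == {1}
        counts = np.zeros(5)
        draws = 20000
        for _ in range(draws):
            a, b = select_parents(pop, ranking, rng)
        # count first-slot picks by identity
            counts[pop.individuals.index(a)] += 1
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_rank_weighting_two_to_one(self, rng):
        # two individuals: rank 1 and rank 2, weights 1 and 1/2
        fits = [(2.0, 0.0), (1.0, 0.0)]
        pop, ranking = _toy_population(fits)
        assert list(ranking.ranks) == [1, 2]
        first = 0
        draws = 30000
        for _ in range(draws):
            a, _ = select_parents(pop, ranking, rng)
            if a is pop.individuals[0]:
                first += 1
        # first slot favours rank 1 with probability 2/3
        assert first / draws == pytest.approx(2 / 3, abs=0.02)

    def test_deterministic_under_seed(self):
        fits = [(float(i), 0.0) for i in range(6)]
        pop, ranking = _toy_population(fits)
        picks1 = [
            select_parents(pop, ranking, np.random.default_rng(s))[0].fitness
            for s in range(20)
        ]
        picks2 = [
            select_parents(pop, ranking, np.random.default_rng(s))[0].fitness
            for s in range(20)
        ]
        assert picks1 == picks2

    def test_population_of_one_rejected(self, rng):
        pop, ranking = _toy_population([(1.0, 1.0)])
        with pytest.raises(ParameterError):
            select_parents(pop, ranking, rng)


class TestCrossover:
    def test_identical_parents_reproduce(self, rng):
        a = Individual("MKVLAE")
        child = crossover_1pt(a, Individual("MKVLAE"), rng)
        assert child.sequence == "MKVLAE"

    def test_fixed_cut_point(self, rng):
        child = crossover_1pt(Individual("AAAA"), Individual("CCCC"), rng, k=2)
        assert child.sequence == "AACC"

    def test_exhaustive_cut_sweep(self, rng):
        a, b = Individual("AAAAAA"), Individual("CCCCCC")
        for k in range(1, 6):
            child = crossover_1pt(a, b, rng, k=k)
            assert child.sequence == "A" * k + "C" * (6 - k)

    def test_length_mismatch(self, rng):
        with pytest.raises(ParameterError):
            crossover_1pt(Individual("AAA"), Individual("CCCC"), rng)


class TestMutate:
    def test_zero_rate_is_identity(self, template, rng):
        assert mutate(template.seed, template, 0.0, rng).sequence == template.seed

    def test_rate_one_changes_every_free_position(self, template, rng):
        out = mutate(template.seed, template, 1.0, rng).sequence
        for pos in template.free_positions:
            assert out[pos - 1] != template.seed[pos - 1]
        for pos in template.fixed_positions:
            assert out[pos - 1] == template.seed[pos - 1]

    def test_output_always_valid(self, template, rng):
        for _ in range(50):
            out = mutate(template.seed, template, 0.3, rng)
            assert validate_sequence(out.sequence, template)


class TestCountEvaluated:
    @pytest.mark.parametrize(
        "pop,gens,expected",
        [(600, 2000, 1_200_000), (8, 15, 120), (2, 1, 2)],
    )
    def test_accounting(self, pop, gens, expected):
        assert count_evaluated(
            GAConfig(population_size=pop, generations=gens)
        ) == expected


def _count_a_fitness(template):
    free = [p - 1 for p in template.free_positions]

    def fitness(seq):
        return (float(sum(seq[i] == "A" for i in free)),)

    return fitness


class TestEvolve:
    def test_zero_generations_returns_evaluated_initial_population(
        self, template, fitness_fn
    ):
        cfg = GAConfig(population_size=10, generations=0, rng_seed=3)
        pop, ranking, history = evolve(template, cfg, fitness_fn)
        assert len(pop) == 10 and pop.generation == 0
        assert all(ind.fitness is not None for ind in pop.individuals)
        assert len(history) == 1

    def test_constant_fitness_makes_whole_population_frontier(self, template):
        cfg = GAConfig(population_size=12, generations=3, rng_seed=3)
        pop, ranking, history = evolve(template, cfg, lambda seq: (1.0, 1.0))
        for rec in history:
            assert rec.frontier_size == 12

    def test_single_objective_toy_reaches_optimum(self):
        """Hill-climbing sanity check: maximising the count of alanines at
        free positions must be monotone and reach the free-position total."""
        from helixgraft.synthetic import FixtureSpec, make_template

        toy = make_template(FixtureSpec(rng_seed=1, seq_length=30, n_fixed=14))
        cfg = GAConfig(
            population_size=50, generations=100, mutation_rate=0.05, rng_seed=42
        )
        pop, ranking, history = evolve(toy, cfg, _count_a_fitness(toy))
        best = [rec.best_components[0] for rec in history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
        assert best[-1] == len(toy.free_positions)

    def test_bitwise_reproducible(self, template, fitness_fn):
        cfg = GAConfig(population_size=20, generations=5, rng_seed=7)
        pop1, _, _ = evolve(template, cfg, fitness_fn)
        pop2, _, _ = evolve(template, cfg, fitness_fn)
        assert [i.sequence for i in pop1.individuals] == [
            i.sequence for i in pop2.individuals
        ]

    def test_population_size_and_conservation_every_generation(
        self, template, fitness_fn
    ):
        seen = []

        def check(gen, pop, ranking):
            seen.append(gen)
            assert len(pop) == 15
            assert conservation_violations(pop, template) == 0

        cfg = GAConfig(population_size=15, generations=8, rng_seed=11)
        evolve(template, cfg, fitness_fn, callback=check)
        assert seen == list(range(9))

    def test_failing_fitness_reports_generation(self, template):
        def bad(seq):
            raise RuntimeError("boom")

        cfg = GAConfig(population_size=5, generations=1, rng_seed=0)
        with pytest.raises(ParameterError, match="generation 0"):
            evolve(template, cfg, bad)
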