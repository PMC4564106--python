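"""Genetic operators and whole training runs."""

import itertools

import numpy as np
import pytest
from scipy import stats

from survarea import (
    FitnessSpec,
    GAConfig,
    Genome,
    MLPArchitecture,
    SurvivalDataset,
    train,
)
from survarea.ann import raw_output
from survarea.genetic import (
    GAState,
    crossover_two_point,
    initialize,
    insert_and_cull,
    mutate_gaussian,
    tournament_select,
)


def make_state(fitnesses):
    pop = [Genome(np.full(3, float(i)), fitness=f) for i, f in enumerate(fitnesses)]
    best = max(pop, key=lambda g: g.fitness).copy()
    state = GAState(pop, list(range(len(pop))), best)
    state._next_birth = len(pop)
    return state


class TestTournament:
    def test_single_member_population(self, rng):
        state = make_state([2.0])
        assert tournament_select(state, rng).fitness == 2.0

    def test_fitter_of_two_picks_wins(self):
        state = make_state([5.0, 1.0])

        class FixedRng:
            def integers(self, lo, hi, size):
                return np.array([0, 1])

        assert tournament_select(state, FixedRng()).fitness == 5.0

    def test_win_rate_is_three_quarters(self, rng):
        # of the 4 equally likely ordered pairs, the fitter wins 3
        state = make_state([5.0, 1.0])
        wins = sum(
            tournament_select(state, rng).fitness == 5.0 for _ in range(10000)
        )
        assert abs(wins / 10000 - 0.75) < 0.02


class TestCrossover:
    def test_no_crossover_yields_clones(self, rng):
        a, b = Genome([1.0, 2.0, 3.0]), Genome([4.0, 5.0, 6.0])
        ca, cb = crossover_two_point(a, b, 0.0, rng)
        np.testing.assert_array_equal(ca.weights, a.weights)
        np.testing.assert_array_equal(cb.weights, b.weights)

    def test_identical_parents_give_identical_children(self, rng):
        a = Genome([1.0, 2.0, 3.0, 4.0])
        ca, cb = crossover_two_point(a, Genome(a.weights.copy()), 1.0, rng)
        np.testing.assert_array_equal(ca.weights, a.weights)
        np.testing.assert_array_equal(cb.weights, a.weights)

    def test_segment_swap(self):
        class FixedRng:
            def random(self):
                return 0.0  # always cross over

            def integers(self, lo, hi, size):
                return np.array([1, 3])

        ca, cb = crossover_two_point(
            Genome([1.0, 2, 3, 4]), Genome([5.0, 6, 7, 8]), 1.0, FixedRng()
        )
        assert ca.weights.tolist() == [1, 6, 7, 4]
        assert cb.weights.tolist() == [5, 2, 3, 8]

    def test_per_position_multisets_preserved(self, rng):
        a = Genome(rng.standard_normal(30))
        b = Genome(rng.standard_normal(30))
        for _ in range(50):
            ca, cb = crossover_two_point(a, b, 1.0, rng)
            for k in range(30):
                assert {ca.weights[k], cb.weights[k]} == {a.weights[k], b.weights[k]}

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            crossover_two_point(Genome([1.0]), Genome([1.0, 2.0]), 1.0, rng)


class TestMutation:
    def test_zero_probability_is_identity(self, rng):
        g = Genome(rng.standard_normal(100))
        out = mutate_gaussian(g, 0.0, 1.5, rng)
        np.testing.assert_array_equal(out.weights, g.weights)

    def test_unmutated_positions_bit_identical(self, rng):
        g = Genome(rng.standard_normal(1000))
        out = mutate_gaussian(g, 0.3, 1.5, rng)
        same = out.weights == g.weights
        assert (out.weights[same] == g.weights[same]).all()
        assert same.sum() > 0 and (~same).sum() > 0

    def test_mutation_count_binomial(self, rng):
        g = Genome(np.zeros(10000))
        out = mutate_gaussian(g, 0.5, 1.5, rng)
        hits = int((out.weights != 0.0).sum())
        lo, hi = stats.binom.interval(0.999, 10000, 0.5)
        assert lo <= hits <= hi


class TestInsertAndCull:
    def test_bad_children_are_the_ones_discarded(self):
        state = make_state([5.0, 4.0, 3.0])
        survivors_before = {id(g) for g in state.population}
        kids = (Genome(np.zeros(3), fitness=1.0), Genome(np.zeros(3), fitness=2.0))
        insert_and_cull(state, (state.population[0], state.population[1]), kids)
        assert state.size == 3
        assert {id(g) for g in state.population} == survivors_before

    def test_best_child_survives_and_updates_best_ever(self):
        state = make_state([5.0, 4.0, 3.0])
        star = Genome(np.ones(3), fitness=9.0)
        insert_and_cull(state, (state.population[0], state.population[1]),
                        (star, Genome(np.zeros(3), fitness=0.0)))
        assert any(g is star for g in state.population)
        assert state.best_ever.fitness == 9.0

    def test_population_max_never_decreases(self, rng):
        state = make_state(list(rng.uniform(0, 10, size=6)))
        for _ in range(50):
            prev_max = max(g.fitness for g in state.population)
            kids = tuple(
                Genome(np.zeros(3), fitness=float(rng.uniform(0, 10)))
                for _ in range(2)
            )
            insert_and_cull(state, (state.population[0], state.population[1]), kids)
            assert max(g.fitness for g in state.population) >= prev_max
            assert state.size == 6

    def test_unevaluated_children_rejected(self):
        state = make_state([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            insert_and_cull(
                state,
                (state.population[0], state.population[1]),
                (Genome(np.zeros(3)), Genome(np.zeros(3))),
            )


def separable_dataset(n_per_side=10, seed=0):
    """One covariate whose sign determines short- vs long-lived."""
    rng = np.random.default_rng(seed)
    import pandas as pd

    times = np.concatenate([rng.uniform(0.5, 2.0, n_per_side),
                            rng.uniform(50.0, 60.0, n_per_side)])
    events = np.concatenate([np.ones(n_per_side), np.zeros(n_per_side)]).astype(int)
    x = np.concatenate([-np.abs(rng.normal(1, 0.3, n_per_side)),
                        np.abs(rng.normal(1, 0.3, n_per_side))])
    return SurvivalDataset(times, events, pd.DataFrame({"x": x}))


class TestTrain:
    arch = MLPArchitecture(1, 4)
    small = GAConfig(population_size=30, generations=20, seed=11)

    def test_initialization_contract(self, rng):
        cfg = GAConfig(population_size=4)
        arch = MLPArchitecture(2, 3)
        state = initialize(arch, cfg, lambda g: 1.0, rng)
        assert state.size == 4
        assert all(g.fitness == 1.0 for g in state.population)
        assert all(len(g) == arch.genome_length for g in state.population)

    def test_separable_data_low_risk_group_is_long_lived(self):
        data = separable_dataset()
        spec = FitnessSpec("maximize", m=5, t_N=data.max_time)
        successes = 0
        for seed in range(10):
            cfg = GAConfig(population_size=50, generations=50, seed=seed)
            best = train(data, spec, self.arch, cfg)
            mask = raw_output(best, self.arch, data.covariates.to_numpy()) > 0
            members_long_lived = data.times[mask] > 10.0
            if mask.sum() >= 5 and members_long_lived.all():
                successes += 1
        assert successes >= 9

    def test_zero_generations_returns_best_of_initial_population(self):
        data = separable_dataset()
        spec = FitnessSpec("maximize", m=1, t_N=data.max_time)
        cfg = GAConfig(population_size=20, generations=0, seed=5)
        best = train(data, spec, self.arch, cfg)
        assert best.fitness is not None and best.fitness >= 0

    def test_fixed_seed_reproducible(self):
        data = separable_dataset()
        spec = FitnessSpec("minimize", m=3, t_N=data.max_time)
        a = train(data, spec, self.arch, self.small)
        b = train(data, spec, self.arch, self.small)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.fitness == b.fitness

    def test_trace_best_fitness_non_decreasing(self):
        data = separable_dataset()
        spec = FitnessSpec("maximize", m=3, t_N=data.max_time)
        trace = []
        train(data, spec, self.arch, self.small, trace=trace)
        best = [row["best_fitness"] for row in trace]
        assert len(best) == self.small.generations + 1
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_min_size_at_least_dataset_size_rejected(self):
        data = separable_dataset(n_per_side=3)
        spec = FitnessSpec("maximize", m=6, t_N=data.max_time)
        with pytest.raises(ValueError):
            train(data, spec, self.arch, self.small)

    def test_degenerate_run_warns(self):
        # m = n-1 with minimize on pure-censoring data: every group scores 0
        import pandas as pd

        data = SurvivalDataset(
            [1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0],
            pd.DataFrame({"x": [0.1, -0.2, 0.3, -0.4]}),
        )
        spec = FitnessSpec("minimize", m=3, t_N=4.0)
        cfg = GAConfig(population_size=8, generations=2, seed=0)
        with pytest.warns(UserWarning, match="minimum size"):
            train(data, spec, MLPArchitecture(1, 2), cfg)
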