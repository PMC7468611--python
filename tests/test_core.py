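import numpy as np
import pytest
from scipy import stats

from samaepi import (
    SamaParams,
    SnpPair,
    breeder_delta,
    breeder_mutation,
    elitist_selection,
    hybrid_crossover,
    initialize_population,
    local_search_step,
    run_sama,
    sls_update_prob,
)
from samaepi.association import FitnessEvaluator

from conftest import ScriptedRng, alpha_vector


class TestInitialization:
    def test_indices_in_range_and_distinct(self, rng):
        for pair in initialize_population(5000, 7, rng):
            assert 1 <= pair.r_p <= 7 and 1 <= pair.r_q <= 7
            assert pair.r_p != pair.r_q

    def test_index_distribution_uniform(self, rng):
        L = 50
        pop = initialize_population(10_000, L, rng)
        counts = np.bincount(
            [i - 1 for p in pop for i in (p.r_p, p.r_q)], minlength=L
        )
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3

    def test_requires_two_snps(self, rng):
        with pytest.raises(ValueError):
            initialize_population(10, 1, rng)


class TestHybridCrossover:
    BEST = SnpPair(121, 82)

    def test_second_coordinate_inherited(self):
        # r1 misses p_c1, r2 hits p_c2: only the second SNP is replaced
        rng = ScriptedRng([0.9, 0.1])
        assert hybrid_crossover(SnpPair(75, 53), self.BEST, 0.8, 0.8, rng).key == (75, 82)

    def test_first_coordinate_inherited(self):
        rng = ScriptedRng([0.1, 0.9])
        assert hybrid_crossover(SnpPair(107, 87), self.BEST, 0.8, 0.8, rng).key == (87, 121)

    def test_both_hits_copy_the_best(self):
        rng = ScriptedRng([0.1, 0.1])
        assert hybrid_crossover(SnpPair(83, 78), self.BEST, 0.8, 0.8, rng) == self.BEST

    def test_zero_probabilities_keep_individual(self, rng):
        x = SnpPair(5, 9)
        for _ in range(50):
            assert hybrid_crossover(x, self.BEST, 0.0, 0.0, rng) == x

    def test_collision_redraws_second_coordinate(self):
        # first inherits best's 121; second stays 121 -> collision -> redraw
        rng = ScriptedRng([0.1, 0.9, 0.5])  # redraw: ceil(0.5*200) = 100
        out = hybrid_crossover(SnpPair(70, 121), self.BEST, 0.8, 0.8, rng, L=200)
        assert out.key == (100, 121)


class TestBreederDelta:
    def test_no_active_bits_gives_zero(self):
        d = breeder_delta(ScriptedRng([[0.9] * 15, 0.1]))
        assert d.delta == 0.0 and d.sign == 1

    def test_single_bit_values_and_sign(self):
        d = breeder_delta(ScriptedRng([alpha_vector(1), 0.9]))
        assert d.delta == 0.5 and d.sign == -1
        d = breeder_delta(ScriptedRng([alpha_vector(15), 0.1]))
        assert d.delta == 2**-15 and d.sign == 1

    def test_support_and_granularity(self, rng):
        for _ in range(2000):
            d = breeder_delta(rng)
            assert 0 <= d.delta <= 1 - 2**-15
            scaled = d.delta * 2**15
            assert scaled == round(scaled)  # multiple of the 2^-15 step


class TestBreederMutation:
    def test_running_offsets_shift_both_coordinates(self):
        # delta = 0.5 on both coordinates, sign '-': offset 10 at range 20
        rng = ScriptedRng([alpha_vector(1), 0.9, alpha_vector(1), 0.9])
        out = breeder_mutation(SnpPair(75, 82), L=200, range_factor=0.1, rng=rng)
        assert out.key == (65, 72)

    def test_zero_delta_keeps_pair(self):
        rng = ScriptedRng([[0.9] * 15, 0.1, [0.9] * 15, 0.1])
        assert breeder_mutation(SnpPair(75, 82), 200, 0.1, rng).key == (75, 82)

    def test_out_of_range_reinitializes_whole_pair(self):
        # first coordinate would land at -2: whole pair redrawn uniformly
        rng = ScriptedRng([alpha_vector(1), 0.9, [0.9] * 15, 0.1, 0.2, 0.6])
        out = breeder_mutation(SnpPair(8, 40), L=200, range_factor=0.1, rng=rng)
        assert out.key == (40, 120)  # ceil(0.2*200), ceil(0.6*200)

    def test_shared_offset_mode_moves_both_by_one_draw(self):
        rng = ScriptedRng([alpha_vector(2), 0.1])  # delta 0.25 -> offset 5, sign +
        out = breeder_mutation(
            SnpPair(30, 60), 200, 0.1, rng, shared_offset=True
        )
        assert out.key == (35, 65)

    def test_outputs_always_in_range(self, rng):
        L = 200
        pair = SnpPair(1, 200)
        for _ in range(100_000):
            pair = breeder_mutation(pair, L, 0.1, rng)
            assert 1 <= pair.r_p <= L and 1 <= pair.r_q <= L and pair.r_p != pair.r_q


class TestLocalSearch:
    def test_zero_steps_returns_input(self, model2_dataset, rng):
        params = SamaParams(M=2, max_ls_steps=0)
        z = SnpPair(1, 2)
        ev = FitnessEvaluator(model2_dataset)
        assert local_search_step(z, ev, model2_dataset.L, params, rng) == z

    def test_never_decreases_fitness(self, model2_dataset, rng):
        ev = FitnessEvaluator(model2_dataset)
        params = SamaParams(M=2, max_ls_steps=10)
        for _ in range(50):
            z = SnpPair(*(rng.choice(model2_dataset.L, 2, replace=False) + 1))
            w = local_search_step(z, ev, model2_dataset.L, params, rng)
            assert ev(w) >= ev(z)

    def test_finds_nearby_true_pair_sometimes(self, model2_dataset):
        """Start one index off the causal pair; some seeds must reach it."""
        t1, t2 = model2_dataset.truth
        start = SnpPair(t1, t2 + 1 if t2 < model2_dataset.L else t2 - 1)
        ev = FitnessEvaluator(model2_dataset)
        params = SamaParams(M=2, max_ls_steps=10)
        hits = sum(
            local_search_step(
                start, ev, model2_dataset.L, params, np.random.default_rng(s)
            )
            == SnpPair(t1, t2)
            for s in range(100)
        )
        assert hits > 0


class TestSlsProbability:
    def test_improvement_resets_to_one(self):
        assert sls_update_prob(0.3, True, 0.5) == 1.0

    @pytest.mark.parametrize("n", range(1, 11))
    def test_geometric_decay_is_exact(self, n):
        p = 1.0
        for _ in range(n):
            p = sls_update_prob(p, False, 0.5)
        assert p == 0.5**n

    def test_decay_vanishes_as_xi_approaches_one(self):
        assert sls_update_prob(0.8, False, 1 - 1e-12) == pytest.approx(0.8)

    def test_rejects_invalid_arguments(self):
        with pytest.raises(ValueError):
            sls_update_prob(0.0, False, 0.5)
        with pytest.raises(ValueError):
            sls_update_prob(0.5, False, 1.0)


class TestElitistSelection:
    FITS = {(54, 63): 40.0, (82, 121): 62.8, (87, 126): 70.0, (50, 60): 30.0}

    def fitness(self, pair):
        return self.FITS[pair.key]

    def test_strictly_better_offspring_replaces(self):
        x, w = SnpPair(121, 82), SnpPair(126, 87)
        assert elitist_selection(x, w, self.fitness) == w

    def test_worse_or_equal_offspring_rejected(self):
        x, w = SnpPair(54, 63), SnpPair(50, 60)
        assert elitist_selection(x, w, self.fitness) == x
        assert elitist_selection(x, x, self.fitness) == x


class TestRunSama:
    def test_history_nondecreasing_and_deterministic(self, model2_dataset):
        params = SamaParams(M=20, max_iterations=8, seed=5)
        a = run_sama(model2_dataset, params)
        b = run_sama(model2_dataset, params)
        assert a.best == b.best and a.history == b.history
        assert all(x <= y for x, y in zip(a.history, a.history[1:]))
        assert len(a.history) == params.max_iterations + 1
        assert a.best_fitness == a.history[-1]

    def test_finds_causal_pair_on_easy_small_dataset(self, model2_dataset):
        params = SamaParams(M=50, max_iterations=20, seed=1)
        result = run_sama(model2_dataset, params)
        assert result.best == SnpPair(*model2_dataset.truth)

    def test_evaluation_budget_bound(self, model2_dataset):
        params = SamaParams(M=10, max_iterations=5, max_ls_steps=4, seed=2)
        result = run_sama(model2_dataset, params)
        # init M + per generation at most M * (HC/DBM offspring + LS proposals + 1)
        bound = params.M + params.max_iterations * params.M * (params.max_ls_steps + 2)
        assert result.evaluations <= result.calls
        assert result.evaluations <= bound

    def test_sls_gating_reduces_work_with_smaller_xi(self, model2_dataset):
        calls = []
        for xi in (0.9, 0.1):
            params = SamaParams(M=30, max_iterations=10, xi=xi, seed=3)
            calls.append(run_sama(model2_dataset, params).calls)
        assert calls[1] < calls[0]

    def test_generation_log_is_written(self, model2_dataset, tmp_path):
        import json

        log = tmp_path / "run.jsonl"
        params = SamaParams(M=10, max_iterations=4, seed=9)
        run_sama(model2_dataset, params, log_path=log)
        lines = [json.loads(l) for l in log.read_text().splitlines()]
        assert len(lines) == 4
        assert {"generation", "best", "best_fitness", "evaluations"} <= set(lines[0])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SamaParams(M=1)
        with pytest.raises(ValueError):
            SamaParams(xi=0.0)
        with pytest.raises(ValueError):
            SamaParams(range_factor=0.0)
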