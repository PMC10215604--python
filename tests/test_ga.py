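"""Chromosome encoding, fitness arithmetic and genetic operators."""

import numpy as np
import pytest

from galslo.ga import (CROSSOVER_GROUPS, Chromosome, Evaluator, FitnessConfig,
                       GaConfig, crossover, enumerate_space, evolve,
                       exhaustive_search, fitness, init_population, mutate,
                       select_parents)
from galslo.ga import EvaluatedIndividual


class TestChromosome:
    @pytest.mark.parametrize("vec,length,leads", [
        ([3, 0, 1, 0, 1, 0, 0, 0, 0, 1, 1, 0, 0], 3, ("II", "avR", "V3", "V4")),
        ([9, 1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0], 9,
         ("I", "II", "avR", "avL", "V1", "V2", "V4")),
        ([5, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1], 5,
         ("I", "III", "avF", "V2", "V4", "V6")),
    ])
    def test_decode(self, vec, length, leads):
        c = Chromosome.from_vector(vec)
        assert c.decode() == (length, leads)

    def test_invalid_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            Chromosome(T_L=0, mask=(1,) * 12)
        with pytest.raises(ValueError):
            Chromosome(T_L=3, mask=(0,) * 12)
        with pytest.raises(ValueError):
            Chromosome.from_vector([3, 1, 0])

    def test_string_roundtrip(self):
        c = Chromosome.from_vector([5, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1])
        assert str(c) == "5,1,0,1,0,0,1,0,1,0,1,0,1"
        assert Chromosome.from_vector(str(c).split(",")) == c


class TestFitness:
    def test_worked_values(self):
        seven = Chromosome(T_L=9, mask=(1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0))
        assert fitness(1.0, 1.0, seven) == pytest.approx(1.912, abs=1e-12)
        one = Chromosome(T_L=1, mask=(1,) + (0,) * 11)
        assert fitness(0.0, 0.0, one) == pytest.approx(-0.012, abs=1e-12)

    def test_zero_penalties_reduce_to_quality_sum(self):
        cfg = FitnessConfig(gamma=0.0, sigma=0.0)
        for vec in ([9, 1] + [1] * 11, [1, 1] + [0] * 11):
            c = Chromosome.from_vector(vec)
            assert fitness(0.3, 0.4, c, cfg) == pytest.approx(0.7, abs=1e-15)

    def test_out_of_range_scores_rejected(self):
        c = Chromosome(T_L=1, mask=(1,) + (0,) * 11)
        with pytest.raises(ValueError):
            fitness(1.2, 0.5, c)
        with pytest.raises(ValueError):
            fitness(0.5, -0.1, c)

    def test_random_triples_match_hand_oracle(self):
        rng = np.random.default_rng(42)
        cfg = FitnessConfig()
        for _ in range(100):
            f1, acc = rng.random(), rng.random()
            T_L = int(rng.integers(1, 10))
            mask = tuple(int(v) for v in rng.integers(0, 2, 12))
            if sum(mask) == 0:
                mask = (1,) + mask[1:]
            c = Chromosome(T_L=T_L, mask=mask)
            oracle = 1.0 * f1 + 1.0 * acc - 0.002 * T_L - 0.01 * sum(mask)
            assert fitness(f1, acc, c) == pytest.approx(oracle, abs=1e-12)

    def test_monotone_complexity_penalty(self):
        base = Chromosome(T_L=2, mask=(1, 1) + (0,) * 10)
        more_leads = Chromosome(T_L=2, mask=(1, 1, 1) + (0,) * 9)
        longer = Chromosome(T_L=3, mask=base.mask)
        f0 = fitness(0.9, 0.9, base)
        assert fitness(0.9, 0.9, more_leads) < f0
        assert fitness(0.9, 0.9, longer) < f0


class TestInitPopulation:
    def test_size_validity_and_determinism(self):
        cfg = GaConfig(seed=5)
        pop = init_population(cfg)
        assert len(pop) == 100
        assert all(1 <= c.T_L <= 9 and c.n_leads >= 1 for c in pop)
        assert pop == init_population(cfg)

    def test_fixed_lead_count_respected(self):
        cfg = GaConfig(fixed_lead_count=3, seed=1)
        assert all(c.n_leads == 3 for c in init_population(cfg))

    def test_restricted_space(self):
        cfg = GaConfig(lengths=(2, 4), leads=(1, 7), seed=0)
        pop = init_population(cfg)
        assert all(c.T_L in (2, 4) for c in pop)
        assert all(set(c.leads) <= {1, 7} for c in pop)


class TestSelection:
    @staticmethod
    def _ev(c, fit):
        return EvaluatedIndividual(chromosome=c, fitness=fit, f1=0.5,
                                   acc=0.5, seed=0)

    def test_top_k_by_fitness(self):
        rng = np.random.default_rng(0)
        pop = init_population(GaConfig(seed=0))
        evaluated = [self._ev(c, float(f)) for c, f in zip(pop, rng.random(100))]
        parents = select_parents(evaluated, 50)
        assert len(parents) == 50
        cut = min(p.fitness for p in parents)
        assert all(ev.fitness <= cut or ev in parents for ev in evaluated)

    def test_tie_breaking_prefers_low_complexity(self):
        lean = Chromosome(T_L=1, mask=(1,) + (0,) * 11)
        fat = Chromosome(T_L=9, mask=(1,) * 12)
        short = Chromosome(T_L=2, mask=(1, 1) + (0,) * 10)
        long_ = Chromosome(T_L=7, mask=(1, 1) + (0,) * 10)
        evs = [self._ev(c, 1.0) for c in (fat, long_, short, lean)]
        ranked = select_parents(evs, 4)
        assert [e.chromosome for e in ranked] == [lean, short, long_, fat]


class TestCrossover:
    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(0)
        p1 = Chromosome(T_L=2, mask=(1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0))
        p2 = Chromosome(T_L=7, mask=(0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1))
        never = GaConfig(group_swap_probs=(0.0,) * 7)
        c1, c2 = crossover(p1, p2, never, rng)
        assert (c1, c2) == (p1, p2)
        always = GaConfig(group_swap_probs=(1.0,) * 7)
        c1, c2 = crossover(p1, p2, always, rng)
        assert (c1, c2) == (p2, p1)

    def test_group_atomicity(self):
        """Each anatomical group's genes travel together from one parent."""
        rng = np.random.default_rng(1)
        cfg = GaConfig()
        p1 = Chromosome(T_L=1, mask=(1,) * 12)
        p2 = Chromosome(T_L=9, mask=(1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0))
        groups = [g for g in CROSSOVER_GROUPS if g is not None]
        for _ in range(10_000):
            for child in crossover(p1, p2, cfg, rng):
                for group in groups:
                    got = tuple(child.mask[lead - 1] for lead in group)
                    src1 = tuple(p1.mask[lead - 1] for lead in group)
                    src2 = tuple(p2.mask[lead - 1] for lead in group)
                    assert got in (src1, src2), "heart-part group split up"

    def test_fixed_count_repair(self):
        rng = np.random.default_rng(2)
        cfg = GaConfig(fixed_lead_count=2)
        p1 = Chromosome(T_L=1, mask=(1, 1) + (0,) * 10)
        p2 = Chromosome(T_L=2, mask=(0,) * 10 + (1, 1))
        for _ in range(200):
            c1, c2 = crossover(p1, p2, cfg, rng)
            assert c1.n_leads == 2 and c2.n_leads == 2


class TestMutation:
    def test_empirical_rates(self):
        rng = np.random.default_rng(3)
        cfg = GaConfig()
        base = Chromosome(T_L=5, mask=(1,) * 12)
        n = 100_000
        tl_changed = 0
        flips = np.zeros(12)
        for _ in range(n):
            m = mutate(base, cfg, rng)
            tl_changed += m.T_L != base.T_L
            flips += np.array(m.mask) != np.array(base.mask)
        assert abs(tl_changed / n - 0.80) < 0.01
        assert np.all(np.abs(flips / n - 0.50) < 0.01)

    def test_validity_closure(self):
        rng = np.random.default_rng(4)
        cfg = GaConfig()
        c = Chromosome(T_L=1, mask=(1,) + (0,) * 11)
        for _ in range(5000):
            c = mutate(c, cfg, rng)
            assert 1 <= c.T_L <= 9 and c.n_leads >= 1

    def test_fixed_length_skips_tl_mutation(self):
        rng = np.random.default_rng(5)
        cfg = GaConfig(fixed_T_L=4, lengths=(4,))
        c = Chromosome(T_L=4, mask=(1, 1) + (0,) * 10)
        assert all(mutate(c, cfg, rng).T_L == 4 for _ in range(100))


class TestEvaluator:
    def test_memoization(self, small_evaluator):
        c = Chromosome(T_L=1, mask=(0, 1, 0, 1) + (0,) * 8)
        first = small_evaluator.evaluate(c)
        n = small_evaluator.n_trainings
        second = small_evaluator.evaluate(c)
        assert first is second
        assert small_evaluator.n_trainings == n

    def test_fitness_field_reproduces_formula(self, small_evaluator):
        c = Chromosome(T_L=2, mask=(1, 1, 0, 0) + (0,) * 8)
        ev = small_evaluator.evaluate(c)
        assert ev.fitness == pytest.approx(fitness(ev.f1, ev.acc, c), abs=1e-12)

    def test_informative_leads_beat_noise_leads(self, small_evaluator):
        informative = Chromosome(T_L=1, mask=(0, 1, 0, 1) + (0,) * 8)
        noise = Chromosome(T_L=1, mask=(1, 0, 1, 0) + (0,) * 8)
        assert small_evaluator.evaluate(informative).fitness \
            > small_evaluator.evaluate(noise).fitness

    def test_missing_cache_entry_is_named(self, small_evaluator):
        cfg = GaConfig(lengths=(1, 8), leads=(1, 2), seed=0)
        with pytest.raises(ValueError, match=r"\(1, 8\)"):
            evolve(small_evaluator, cfg)


class TestEvolve:
    def test_population_bookkeeping_and_elitism(self, small_cache):
        ev = Evaluator(small_cache, head="mlp", seed=2,
                       head_kwargs={"epochs": 10, "hidden": (16,)})
        cfg = GaConfig(lengths=(1, 2, 3), leads=(1, 2, 3, 4), seed=9)
        best, history = evolve(ev, cfg)
        assert all(h["population_size"] == 100 for h in history)
        run_best = -np.inf
        for h in history:
            run_best = max(run_best, h["max_fitness"])
            assert max(h["fitnesses"]) == h["max_fitness"]
        assert best.fitness == pytest.approx(run_best)
        assert len(history) <= cfg.max_generations + 1

    def test_matches_exhaustive_optimum_single_seed(self, small_cache):
        ev = Evaluator(small_cache, head="mlp", seed=3,
                       head_kwargs={"epochs": 10, "hidden": (16,)})
        cfg = GaConfig(lengths=(1, 2, 3), leads=(1, 2, 3, 4), seed=11)
        assert len(enumerate_space(cfg)) == 45
        best, _ = evolve(ev, cfg)
        assert best.fitness == exhaustive_search(ev, cfg).fitness

    def test_composition_identity_enforced(self):
        with pytest.raises(ValueError, match="population size"):
            GaConfig(n_parents=40)
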