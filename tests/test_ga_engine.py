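"""Evolutionary operators, fitness arithmetic and convergence rules."""

import itertools

import numpy as np
import pytest

from triagonist import design_scoring as ds
from triagonist.ga_engine import (
    FitnessComponents,
    GAConfig,
    Individual,
    adaptive_mutation_rate,
    check_convergence,
    crossover,
    draw_mutation_event,
    evolve,
    fitness,
    initialize_population,
    mutate,
    repair,
    tournament_select,
)
from triagonist.seqio import TokenSeq, tokenize
from triagonist.synthdata import planted_oracle

SMALL = GAConfig(pop_size=12, max_generations=4, seed=0)


def make_individual(seq_text, total):
    return Individual(seq=tokenize(seq_text),
                      fitness=FitnessComponents(0, 0.5, 0.5, 0.5, 0.5, 0.5, total))


class TestFitness:
    def test_hand_computed_components(self):
        res = fitness(tokenize("ACD"), np.array([0.6, 0.64, 0.52]),
                      ds.PlausibilityResult(1, 1, 1, 1, 1.0, True),
                      novelty=1.0, diversity=1.0, config=GAConfig())
        assert res.h_active == 3
        assert res.p_mean == pytest.approx((0.6 + 0.64 + 0.52) / 3)
        assert res.p_min == pytest.approx(0.52)
        assert res.total == pytest.approx(3 + res.p_mean + 0.52 + 1 + 1 + 1)

    def test_no_receptor_above_threshold(self):
        res = fitness(tokenize("ACD"), np.array([0.1, 0.4, 0.49]),
                      ds.PlausibilityResult(0, 0, 0, 0, 0.4, True),
                      novelty=0.2, diversity=0.3, config=GAConfig())
        assert res.h_active == 0

    def test_zero_components_zero_total(self):
        res = fitness(tokenize("ACD"), np.array([0.01, 0.02, 0.03]),
                      ds.PlausibilityResult(0, 0, 0, 0, 0.0, False),
                      novelty=0.0, diversity=0.0,
                      config=GAConfig(fitness_weights=(1, 0, 0, 1, 1, 1)))
        assert res.total == pytest.approx(0.0)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            fitness(tokenize("ACD"), np.array([0.0, 0.5, 0.5]),
                    ds.PlausibilityResult(1, 1, 1, 1, 1.0, True), 1, 1, GAConfig())


class TestTournament:
    def test_k_equals_population_selects_global_best(self, rng):
        pop = [make_individual("ACDEF", t) for t in (1.0, 5.0, 3.0)]
        for _ in range(10):
            assert tournament_select(pop, k=3, rng=rng) is pop[1]

    def test_population_smaller_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            tournament_select([make_individual("ACD", 1.0)], k=3, rng=rng)

    def test_selection_frequencies_match_subset_enumeration(self):
        # 5 members with distinct fitness; the best of each 3-subset wins,
        # so P(member i selected) = (# 3-subsets where i is max) / C(5,3)
        totals = [0.1, 3.0, 1.0, 2.0, 5.0]
        pop = [make_individual("ACDEF", t) for t in totals]
        expected = np.zeros(5)
        subsets = list(itertools.combinations(range(5), 3))
        for sub in subsets:
            expected[max(sub, key=lambda i: totals[i])] += 1
        expected /= len(subsets)
        rng = np.random.default_rng(0)
        counts = np.zeros(5)
        n = 10_000
        for _ in range(n):
            winner = tournament_select(pop, k=3, rng=rng)
            counts[pop.index(winner)] += 1
        assert np.allclose(counts / n, expected, atol=0.02)


class _FixedCutRng:
    """Stub rng whose integers() returns the midpoint of its range."""

    def integers(self, lo, hi=None):
        lo, hi = (0, lo) if hi is None else (lo, hi)
        return (lo + hi) // 2

    def random(self):
        return 0.0


class TestCrossover:
    def test_midpoint_cut_of_identical_parents_returns_parents(self):
        p = tokenize("ACDEFGHIKL")
        c1, c2 = crossover(p, p, _FixedCutRng())
        assert c1 == p and c2 == p

    def test_token_count_conserved(self, rng):
        from conftest import random_tokenseq
        for _ in range(200):
            a = random_tokenseq(rng, 5, 30)
            b = random_tokenseq(rng, 5, 30)
            c1, c2 = crossover(a, b, rng)
            assert len(c1) + len(c2) == len(a) + len(b)

    def test_children_are_prefix_suffix_exchanges(self, rng):
        a, b = tokenize("AAAAAAAA"), tokenize("CCCCCCCC")
        c1, c2 = crossover(a, b, rng)
        assert set(c1.tokens) <= {"A", "C"}
        t1 = "".join(c1.tokens)
        assert t1 == "A" * t1.count("A") + "C" * t1.count("C")

    def test_short_parent_rejected(self, rng):
        with pytest.raises(ValueError):
            crossover(tokenize("A"), tokenize("ACDEF"), rng)


class TestMutation:
    def test_zero_rate_is_identity(self, rng):
        s = tokenize("ACDEFGHIKL")
        cfg = GAConfig(mutation_rate=0.0)
        assert mutate(s, cfg, 1.0, rng) == s

    def test_certain_point_mutation_changes_one_position(self, rng):
        s = tokenize("ACDEFGHIKL")
        cfg = GAConfig(mutation_rate=1.0, mutation_mix=(1.0, 0.0, 0.0))
        for _ in range(20):
            out = mutate(s, cfg, 1.0, rng)
            assert len(out) == len(s)
            assert sum(a != b for a, b in zip(out.tokens, s.tokens)) <= 1

    def test_conservative_event_stays_in_class(self, rng):
        s = tokenize("LLLLLLLLLL")
        cfg = GAConfig(mutation_rate=1.0, mutation_mix=(0.0, 1.0, 0.0))
        for _ in range(20):
            out = mutate(s, cfg, 1.0, rng)
            assert all(t in "AVLIM" for t in out.tokens)

    def test_modified_event_introduces_bracket_token(self, rng):
        s = tokenize("ACDEFGHIKL")
        cfg = GAConfig(mutation_rate=1.0, mutation_mix=(0.0, 0.0, 1.0))
        out = mutate(s, cfg, 1.0, rng)
        assert any(len(t) > 1 for t in out.tokens)

    def test_event_mix_frequencies(self):
        rng = np.random.default_rng(42)
        counts = np.bincount(
            [draw_mutation_event(rng, (0.7, 0.2, 0.1)) for _ in range(10_000)],
            minlength=3) / 10_000
        assert np.allclose(counts, [0.7, 0.2, 0.1], atol=0.02)

    def test_adaptive_rate_doubles_and_caps(self):
        cfg = GAConfig(mutation_rate=0.1)
        assert adaptive_mutation_rate(cfg, 0.5) == pytest.approx(0.1)
        assert adaptive_mutation_rate(cfg, 0.1) == pytest.approx(0.2)
        cfg2 = GAConfig(mutation_rate=0.25)
        assert adaptive_mutation_rate(cfg2, 0.1) == pytest.approx(0.3)


class TestRepair:
    def _parents(self):
        glucagon = ds.native_hormones()["glucagon"]
        glp1 = ds.native_hormones()["GLP1"]
        return (Individual(seq=glucagon,
                           fitness=FitnessComponents(1, .5, .5, .8, .5, .5, 3.0)),
                Individual(seq=glp1,
                           fitness=FitnessComponents(1, .5, .5, .8, .5, .5, 2.0)))

    def test_overlong_child_trimmed_with_prefix_preserved(self, rng):
        parents = self._parents()
        child = TokenSeq(tuple(parents[0].seq.tokens + parents[1].seq.tokens))
        cfg = GAConfig()
        out = repair(child, parents, cfg, rng=rng)
        assert len(out) <= cfg.len_max
        if len(out) == cfg.len_max:
            assert out.tokens[:cfg.len_max] == child.tokens[:cfg.len_max] \
                or ds.plausibility(out).pass_flag

    def test_valid_child_unchanged(self, rng):
        parents = self._parents()
        child = parents[0].seq  # native glucagon: in range, plausible
        cfg = GAConfig(len_min=25, len_max=35)
        assert repair(child, parents, cfg, rng=rng) == child

    def test_repair_sweep_yields_plausible_population(self, rng):
        parents = self._parents()
        cfg = GAConfig()
        for _ in range(100):
            c1, c2 = crossover(parents[0].seq, parents[1].seq, rng)
            child = mutate(c1, cfg, 1.0, rng)
            out = repair(child, parents, cfg, rng=rng)
            assert cfg.len_min <= len(out) <= cfg.len_max
            assert ds.plausibility(out).pass_flag


class TestConvergence:
    def test_published_style_trajectory_converges(self):
        improvements = [1.369, 0.893, 0.05, 0.03, 0.02]
        best = list(np.cumsum([10.0] + improvements))
        cfg = GAConfig(max_generations=50)
        # not converged while a large improvement is inside the window
        stop, _ = check_convergence(best[:4], [0.5] * 4, cfg)
        assert not stop
        stop, reason = check_convergence(best, [0.5, 0.51, 0.52, 0.53, 0.5, 0.52], cfg)
        assert stop and reason == "converged"

    def test_monotone_large_improvements_run_to_cap(self):
        cfg = GAConfig(max_generations=50)
        best = list(np.cumsum([1.0] * 49))
        div = list(np.linspace(0.9, 0.5, 49))
        stop, _ = check_convergence(best, div, cfg)
        assert not stop
        best50 = list(np.cumsum([1.0] * 50))
        stop, reason = check_convergence(best50, div + [0.49], cfg)
        assert stop and reason == "max_gen"

    def test_constant_diversity_stagnates(self):
        cfg = GAConfig(max_generations=50)
        best = list(np.cumsum([1.0] * 12))
        stop, reason = check_convergence(best, [0.5] * 12, cfg)
        assert stop and reason == "stagnated"

    def test_fitness_threshold_stop(self):
        cfg = GAConfig(fitness_threshold=5.0)
        stop, reason = check_convergence([6.0], [0.5], cfg)
        assert stop and reason == "fitness_threshold"


class TestInitialization:
    def test_population_size_lengths_and_plausibility(self):
        cfg = GAConfig(pop_size=20, seed=3)
        rng = np.random.default_rng(cfg.seed)
        pop = initialize_population(cfg, rng)
        assert len(pop) == 20
        for ind in pop:
            assert cfg.len_min <= len(ind.seq) <= cfg.len_max
            assert ds.plausibility(ind.seq).pass_flag

    def test_fixed_length_config(self):
        cfg = GAConfig(pop_size=5, len_min=30, len_max=30, seed=1)
        pop = initialize_population(cfg, np.random.default_rng(1))
        assert all(len(ind.seq) == 30 for ind in pop)

    def test_same_seed_identical_population(self):
        cfg = GAConfig(pop_size=8, seed=9)
        p1 = initialize_population(cfg, np.random.default_rng(9))
        p2 = initialize_population(cfg, np.random.default_rng(9))
        assert [i.seq for i in p1] == [i.seq for i in p2]


class TestEvolve:
    @pytest.fixture(scope="class")
    def ga_run(self):
        oracle = planted_oracle(0)
        training = list(ds.native_hormones().values())
        cfg = GAConfig(pop_size=16, max_generations=6, seed=5,
                       convergence_eps=-1.0)  # run all generations
        return evolve(cfg, oracle, training), cfg

    def test_best_fitness_non_decreasing(self, ga_run):
        result, _ = ga_run
        best = [g["best_fitness"] for g in result.generation_stats]
        assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(best, best[1:]))

    def test_population_size_and_constraints_maintained(self, ga_run):
        result, cfg = ga_run
        assert len(result.population) == cfg.pop_size
        for ind in result.population:
            assert cfg.len_min <= len(ind.seq) <= cfg.len_max
            assert ds.plausibility(ind.seq).pass_flag

    def test_fixed_seed_reproducible(self, ga_run):
        result, cfg = ga_run
        oracle = planted_oracle(0)
        training = list(ds.native_hormones().values())
        again = evolve(cfg, oracle, training)
        assert again.best_seq == result.best_seq
        assert again.generation_stats == result.generation_stats
        assert again.stop_reason == result.stop_reason
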