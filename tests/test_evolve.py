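"""Genetic-algorithm operators: exact semantics and sampling statistics."""

import math

import numpy as np
import pytest
import scipy.stats

from ucgmem.evolve import (
    GAConfig,
    Genome,
    Population,
    TargetSpec,
    UNFIT_COST,
    cost,
    crossover_sp,
    geometric_repair,
    init_population,
    membrane_bounds,
    mutate_adaptive_gaussian,
    run_evolution,
    select_rws,
    step_generation,
)
from ucgmem.observables import Profile1D, PropertyReport

GENES6 = ("epsilon", "r_min", "r_shift_on", "r_cut", "k_bond", "k_angle")


def toy_population(costs):
    genomes = [Genome(np.full(6, 1.0), cost=c) for c in costs]
    return Population(genomes, gene_names=GENES6)


class TestInit:
    def test_deterministic_and_in_bounds(self):
        b = membrane_bounds()
        p1 = init_population(96, b, seed=5)
        p2 = init_population(96, b, seed=5)
        for g1, g2 in zip(p1.genomes, p2.genomes):
            assert np.array_equal(g1.genes, g2.genes)
        arr = np.stack([g.genes for g in p1.genomes])
        assert np.all(arr >= p1.bounds[:, 0]) and np.all(arr <= p1.bounds[:, 1])

    def test_geometric_ordering_holds(self):
        pop = init_population(96, membrane_bounds(), seed=1)
        for g in pop.genomes:
            eps, r_min, r1, rc, kb, ka = g.genes
            assert r_min < r1 < rc

    def test_different_seeds_differ(self):
        p1 = init_population(8, membrane_bounds(), seed=1)
        p2 = init_population(8, membrane_bounds(), seed=2)
        assert not np.array_equal(p1.genomes[0].genes, p2.genomes[0].genes)

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError):
            init_population(7, membrane_bounds(), seed=0)


class TestCost:
    def _exact_report(self, targets):
        return PropertyReport(
            apl=targets.apl, ka=targets.ka, line_tension=targets.line_tension,
            kc=targets.kc, ptt=targets.ptt,
            rdf=targets.rdf_ref.normalize(),
            density=targets.density_ref.normalize(),
        )

    def test_zero_cost_at_exact_targets(self):
        targets = TargetSpec.default()
        rep = self._exact_report(targets)
        c = cost(rep, targets)
        assert c.total == pytest.approx(0.0, abs=1e-12)

    def test_single_property_deviation_arithmetic(self):
        targets = TargetSpec.default()
        rep = self._exact_report(targets)
        rep.apl = 0.74
        c = cost(rep, targets)
        assert c.cost1 == pytest.approx(0.15 * (0.74 / 0.68 - 1.0) ** 2, rel=1e-12)
        assert c.cost1 == pytest.approx(1.168e-3, rel=1e-3)

    def test_weights_sum_to_one(self):
        t = TargetSpec()
        assert 5 * t.w_scalar + 2 * t.w_dist == pytest.approx(1.0)

    def test_nonfinite_property_flags_unfit(self):
        targets = TargetSpec.default()
        rep = self._exact_report(targets)
        rep.ka = math.inf
        assert cost(rep, targets).total >= UNFIT_COST

    def test_partial_tier_skips_missing(self):
        targets = TargetSpec.default()
        rep = PropertyReport(apl=0.68)
        c = cost(rep, targets)
        assert c.total == pytest.approx(0.0, abs=1e-12)
        assert set(c.terms) == {"apl"}


class TestSelection:
    def test_probabilities_three_to_one(self):
        # costs chosen so fitnesses are 3 and 1 -> P = 0.75 / 0.25
        pop = toy_population([1.0 / 3.0, 1.0])
        picks = select_rws(pop, 100_000, seed=8)
        frac0 = np.mean([p.cost == pytest.approx(1.0 / 3.0) for p in picks])
        # 3 sigma of a binomial with p = 0.75, n = 1e5
        sigma = math.sqrt(0.75 * 0.25 / 100_000)
        assert abs(frac0 - 0.75) < 3 * sigma + 1e-4

    def test_chi_square_against_formula(self):
        costs = [0.5, 1.0, 2.0, 4.0]
        pop = toy_population(costs)
        fitness = 1.0 / (np.array(costs) + 1e-6)
        probs = fitness / fitness.sum()
        n = 100_000
        picks = select_rws(pop, n, seed=3)
        got = np.array(picks)
        counts = np.array([sum(1 for p in picks if p.cost == c) for c in costs])
        stat = scipy.stats.chisquare(counts, probs * n)
        assert stat.pvalue > 0.01

    def test_equal_fitness_uniform(self):
        genomes = [Genome(np.full(6, float(i)), cost=1.0) for i in range(4)]
        pop = Population(genomes, gene_names=GENES6)
        picks = select_rws(pop, 40_000, seed=2)
        counts = np.array([sum(1 for p in picks if p.genes[0] == i)
                           for i in range(4)])
        stat = scipy.stats.chisquare(counts)
        assert stat.pvalue > 0.01

    def test_all_unfit_rejected(self):
        pop = toy_population([UNFIT_COST, UNFIT_COST])
        with pytest.raises(ValueError):
            select_rws(pop, 10, seed=0)


class TestCrossover:
    def test_cut_semantics(self):
        a = Genome(np.array([1.0, 2, 3, 4, 5, 6]))
        b = Genome(np.array([10.0, 20, 30, 40, 50, 60]))
        # scan seeds until the cut lands at k=3, then check the exchange
        for seed in range(100):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(1, 6))
            ca, cb = crossover_sp(a, b, np.random.default_rng(seed),
                                  gene_names=("a", "b", "c", "d", "e", "f"))
            assert np.array_equal(ca.genes, np.concatenate([a.genes[:k], b.genes[k:]]))
            assert np.array_equal(cb.genes, np.concatenate([b.genes[:k], a.genes[k:]]))
            if k == 3:
                assert np.array_equal(ca.genes, [1, 2, 3, 40, 50, 60])

    def test_identical_parents_identical_children(self):
        a = Genome(np.array([1.0, 2, 3, 4, 5, 6]))
        ca, cb = crossover_sp(a, a, seed=3, gene_names=("a",) * 6)
        assert np.array_equal(ca.genes, a.genes)
        assert np.array_equal(cb.genes, a.genes)

    def test_gene_multiset_conserved(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            a = Genome(rng.uniform(0, 1, 6))
            b = Genome(rng.uniform(0, 1, 6))
            ca, cb = crossover_sp(a, b, seed, gene_names=("a",) * 6)
            before = np.sort(np.concatenate([a.genes, b.genes]))
            after = np.sort(np.concatenate([ca.genes, cb.genes]))
            assert np.allclose(before, after)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            crossover_sp(Genome(np.array([1.0])), Genome(np.array([2.0])),
                         seed=0, gene_names=("a",))


class TestMutation:
    def test_zero_rate_no_change(self):
        g = Genome(np.array([1.0, 2, 3, 4, 5, 6]))
        out = mutate_adaptive_gaussian(g, np.ones(6), 0.0, seed=1,
                                       gene_names=("a",) * 6)
        assert np.array_equal(out.genes, g.genes)

    def test_zero_sigma_no_change(self):
        g = Genome(np.array([1.0, 2, 3, 4, 5, 6]))
        out = mutate_adaptive_gaussian(g, np.zeros(6), 1.0, seed=1,
                                       gene_names=("a",) * 6)
        assert np.array_equal(out.genes, g.genes)

    def test_trigger_rate_matches_pm(self):
        pm = 0.05
        n_trials = 100_000
        rng = np.random.default_rng(77)
        flipped = 0
        g = Genome(np.zeros(10))
        for _ in range(n_trials // 10):
            out = mutate_adaptive_gaussian(g, np.ones(10), pm, rng,
                                           gene_names=("x",) * 10)
            flipped += np.sum(out.genes != 0.0)
        frac = flipped / n_trials
        sigma = math.sqrt(pm * (1 - pm) / n_trials)
        assert abs(frac - pm) < 3 * sigma + 1e-4

    def test_bounds_respected_after_mutation(self):
        b = membrane_bounds()
        pop = init_population(32, b, seed=0)
        rng = np.random.default_rng(5)
        for g in pop.genomes:
            out = mutate_adaptive_gaussian(g, 100 * np.ones(6), 1.0, rng,
                                           gene_names=pop.gene_names,
                                           bounds=pop.bounds)
            assert np.all(out.genes >= pop.bounds[:, 0] - 1e-9)
            assert np.all(out.genes <= pop.bounds[:, 1] + 1e-9)
            eps, r_min, r1, rc, kb, ka = out.genes
            assert r_min < r1 < rc


class TestRepair:
    def test_sorts_violated_ordering(self):
        genes = np.array([15.0, 2.0, 1.5, 1.0, 2000.0, 260.0])
        out = geometric_repair(genes, GENES6)
        assert out[1] < out[2] < out[3]
        assert set(np.round(out[[1, 2, 3]], 6)) == {1.0, 1.5, 2.0}


def quadratic_evaluator(center=0.3):
    def ev(genes, generation, index):
        return float(np.sum((genes - center) ** 2))
    return ev


class TestGenerationLoop:
    BOUNDS = np.tile([[0.0, 1.0]], (6, 1))
    NAMES = ("g1", "g2", "g3", "g4", "g5", "g6")

    def test_population_size_invariant(self):
        pop = init_population(16, self.BOUNDS, seed=0, gene_names=self.NAMES)
        cfg = GAConfig(pop_size=16, pm=0.1, seed=0)
        ev = quadratic_evaluator()
        for _ in range(10):
            pop = step_generation(pop, ev, cfg)
            assert pop.size == 16

    def test_elitism_monotonic_best_cost(self):
        pop = init_population(16, self.BOUNDS, seed=1, gene_names=self.NAMES)
        cfg = GAConfig(pop_size=16, pm=0.2, elitism=2, seed=1)
        ev = quadratic_evaluator()
        best = math.inf
        for _ in range(15):
            pop = step_generation(pop, ev, cfg)
            cur = min(g.cost for g in pop.genomes if g.cost is not None)
            assert cur <= best + 1e-12
            best = min(best, cur)

    def test_failing_evaluator_marks_unfit_and_continues(self):
        def flaky(genes, generation, index):
            if index == 0:
                raise RuntimeError("simulated failure")
            return float(np.sum(genes**2))

        pop = init_population(8, self.BOUNDS, seed=2, gene_names=self.NAMES)
        cfg = GAConfig(pop_size=8, seed=2)
        out = step_generation(pop, flaky, cfg)
        assert out.size == 8

    def test_toy_quadratic_converges(self):
        """Mean cost decreases and the threshold 1e-3 is reached within 50
        generations at population 32 (seeded)."""
        cfg = GAConfig(pop_size=32, pm=0.1, max_iters=50, threshold=1e-3,
                       elitism=2, seed=7)
        history = run_evolution(cfg, quadratic_evaluator(),
                                bounds=self.BOUNDS, gene_names=self.NAMES)
        assert history[-1]["elite_mean_cost"] < 1e-3
        assert len(history) <= 50
        assert history[-1]["mean_cost"] < history[0]["mean_cost"]

    def test_infinite_threshold_runs_all_iters(self):
        cfg = GAConfig(pop_size=8, max_iters=7, threshold=0.0, seed=3)
        history = run_evolution(cfg, quadratic_evaluator(),
                                bounds=self.BOUNDS, gene_names=self.NAMES)
        assert len(history) == 7

    def test_restart_reproduces_history(self):
        cfg = GAConfig(pop_size=8, max_iters=5, seed=11)
        h1 = run_evolution(cfg, quadratic_evaluator(), bounds=self.BOUNDS,
                           gene_names=self.NAMES)
        h2 = run_evolution(cfg, quadratic_evaluator(), bounds=self.BOUNDS,
                           gene_names=self.NAMES)
        for a, b in zip(h1, h2):
            assert a["best_cost"] == b["best_cost"]
            assert np.array_equal(a["best_genes"], b["best_genes"])
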