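"""Update rules checked against analytic oracles; budget and elitism."""

import numpy as np
import pytest

from xdream.optimizers import (
    FDGDConfig,
    FDGDOptimizer,
    GAConfig,
    GeneticOptimizer,
    NESConfig,
    NESOptimizer,
    ScoredPopulation,
    fdgd_propose,
    ga_propose,
    nes_propose,
    nes_utilities,
)


def _population(rng, n=20, d=4):
    return [rng.normal(0, 1, d) for _ in range(n)]


class TestGeneticAlgorithm:
    def test_full_elitism_reproduces_population_exactly(self, rng):
        codes = _population(rng)
        config = GAConfig(population_size=20, n_elites=20)
        pop = ScoredPopulation(codes, rng.uniform(0, 1, 20))
        new = ga_propose(pop, config, rng)
        for old, kept in zip(codes, new):
            assert np.array_equal(old, kept)

    def test_dominating_parent_without_mutation_clones_best(self, rng):
        codes = _population(rng)
        scores = np.arange(20.0)
        config = GAConfig(
            population_size=20,
            n_elites=0,
            mutation_rate=0.0,
            heritability=1.0,
            selectivity=1e6,
        )
        new = ga_propose(ScoredPopulation(codes, scores), config, rng)
        for child in new:
            assert np.array_equal(child, codes[19])

    def test_tied_scores_fall_back_to_uniform_parents(self, rng):
        codes = _population(rng)
        config = GAConfig(population_size=20)
        new = ga_propose(ScoredPopulation(codes, np.ones(20)), config, rng)
        assert len(new) == 20

    def test_elite_ties_broken_by_lower_index(self, rng):
        codes = _population(rng, n=4)
        config = GAConfig(population_size=4, n_elites=1, mutation_rate=1.0)
        new = ga_propose(ScoredPopulation(codes, np.array([1.0, 1.0, 0.0, 0.0])), config, rng)
        assert np.array_equal(new[0], codes[0])

    def test_converges_to_quadratic_optimum(self):
        """Maximizing -||c - c*||^2 in 2-D reaches c* within 0.1."""
        c_star = np.array([1.5, -0.7])
        rng = np.random.default_rng(3)
        opt = GeneticOptimizer(_population(rng, n=20, d=2), GAConfig(), np.random.default_rng(4))
        best, best_f = None, -np.inf
        for _ in range(200):
            codes = opt.ask()
            scores = [-float(np.sum((c - c_star) ** 2)) for c in codes]
            gen_best = int(np.argmax(scores))
            if scores[gen_best] > best_f:
                best_f, best = scores[gen_best], codes[gen_best]
            opt.tell(scores)
        assert np.linalg.norm(best - c_star) < 0.1

    def test_elitist_noiseless_best_is_monotone(self, rng):
        opt = GeneticOptimizer(_population(rng, d=3), GAConfig(), rng)
        f = lambda c: -float(np.sum(c**2))
        bests = []
        for _ in range(50):
            codes = opt.ask()
            scores = [f(c) for c in codes]
            bests.append(max(scores))
            opt.tell(scores)
        assert all(b >= a for a, b in zip(bests, bests[1:]))

    def test_population_size_budget(self, rng):
        opt = GeneticOptimizer(_population(rng), GAConfig(), rng)
        assert opt.per_step_budget == 20
        assert len(opt.ask()) == 20

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            GAConfig(mutation_rate=1.5)
        with pytest.raises(ValueError):
            GAConfig(n_elites=25)


class TestFDGD:
    def test_central_difference_exact_for_linear_fitness(self):
        """For f(c) = w . c the directional central difference is exact."""
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 6)
        current = rng.normal(0, 1, 6)
        config = FDGDConfig(n_pairs=1, perturbation_size=0.37, learning_rate=1.0)
        opt = FDGDOptimizer(current, config, np.random.default_rng(1))
        probes = opt.ask()
        u = (probes[0] - current) / config.perturbation_size
        diff = (float(w @ probes[0]) - float(w @ probes[1])) / (2 * config.perturbation_size)
        assert diff == pytest.approx(float(w @ u), rel=1e-12)
        opt.tell([float(w @ p) for p in probes])
        assert np.allclose(opt.current, current + config.learning_rate * diff * u)

    def test_constant_fitness_leaves_code_unchanged(self, rng):
        current = rng.normal(0, 1, 5)
        new = fdgd_propose(current, FDGDConfig(n_pairs=4), lambda c: 1.0, rng)
        assert np.allclose(new, current)

    def test_gradient_estimate_aligns_with_analytic_gradient(self):
        """Quadratic fitness, 200 antithetic pairs: cosine >= 0.95."""
        A = np.diag([1.0, 2.0, 3.0, 4.0])
        c = np.array([1.0, -1.0, 0.5, 2.0])
        grad = -2 * A @ c
        config = FDGDConfig(n_pairs=200, perturbation_size=1e-3, learning_rate=1.0)
        new = fdgd_propose(c, config, lambda x: -float(x @ A @ x), np.random.default_rng(2))
        g_hat = (new - c) / config.learning_rate
        cosine = g_hat @ grad / (np.linalg.norm(g_hat) * np.linalg.norm(grad))
        assert cosine >= 0.95

    def test_budget_is_two_evaluations_per_pair(self, rng):
        opt = FDGDOptimizer(np.zeros(3), FDGDConfig(n_pairs=7), rng)
        assert opt.per_step_budget == 14
        assert len(opt.ask()) == 14

    def test_non_finite_score_rejected(self, rng):
        opt = FDGDOptimizer(np.zeros(3), FDGDConfig(n_pairs=1), rng)
        opt.ask()
        with pytest.raises(ValueError, match="finite"):
            opt.tell([np.nan, 1.0])


class TestNES:
    def test_symmetric_fitness_gives_vanishing_mean_update(self):
        """f depending only on ||eps|| has zero expected update."""
        config = NESConfig(n_samples=5000, sigma=0.5, learning_rate=1.0)
        new = nes_propose(
            np.zeros(5), config, lambda c: -float(np.sum(c**2)), np.random.default_rng(7)
        )
        assert np.linalg.norm(new) < 0.05

    def test_update_aligns_with_linear_gradient(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 20)
        config = NESConfig(n_samples=10_000, sigma=0.5, learning_rate=1.0)
        new = nes_propose(np.zeros(20), config, lambda c: float(w @ c), np.random.default_rng(1))
        cosine = new @ w / (np.linalg.norm(new) * np.linalg.norm(w))
        assert cosine >= 0.95

    def test_fixed_seed_is_bit_reproducible(self):
        config = NESConfig(n_samples=50, sigma=0.3, learning_rate=0.7)
        f = lambda c: float(np.sum(c))
        a = nes_propose(np.ones(4), config, f, np.random.default_rng(9))
        b = nes_propose(np.ones(4), config, f, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_tied_scores_give_zero_update(self, rng):
        opt = NESOptimizer(np.ones(4), NESConfig(n_samples=10), rng)
        opt.ask()
        opt.tell(np.ones(10))
        assert np.array_equal(opt.current, np.ones(4))

    def test_utilities_are_zero_sum_and_monotone(self, rng):
        scores = rng.normal(0, 1, 15)
        u = nes_utilities(scores, rank_based=True)
        assert abs(u.sum()) < 1e-12
        order = np.argsort(scores)
        assert np.all(np.diff(u[order]) >= 0)

    def test_budget_matches_sample_count(self, rng):
        opt = NESOptimizer(np.zeros(3), NESConfig(n_samples=13), rng)
        assert opt.per_step_budget == 13
        assert len(opt.ask()) == 13
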