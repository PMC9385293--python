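"""Swarm velocity/step contracts, colony probabilities and pheromone update,
FinalBest recombination, and the wrapper fitness (cross-checked against sklearn)."""

import numpy as np
import pytest
from sklearn.neighbors import NearestCentroid

from mpalesion.psaco import (
    ColonyState,
    HybridState,
    Particle,
    PsacoConfig,
    SwarmParams,
    _nearest_centroid_accuracy,
    _stratified_folds,
    aco_construct_solution,
    aco_selection_probabilities,
    aco_update_pheromone,
    decode_position,
    feature_fitness,
    fisher_scores,
    hybrid_select_finalbest,
    init_swarm,
    pso_step,
    pso_velocity_update,
    run_psaco_feature_selection,
)
from mpalesion.synthetic_data import generate_feature_selection_problem


class PinnedRng:
    """Stand-in generator returning a fixed uniform value (synthetic test double)."""

    def __init__(self, value: float):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


def make_particle(position, velocity, personal_best, fitness=0.0):
    return Particle(
        np.asarray(position, float), np.asarray(velocity, float),
        np.asarray(personal_best, float), fitness,
    )


class TestVelocityUpdate:
    def test_pure_inertia(self, rng):
        p = make_particle([0.3, -0.4], [0.2, -0.1], [0.3, -0.4])
        params = SwarmParams(delta=1.0, l1=0.0, l2=0.0, v_max=10, n_dims=2)
        out = pso_velocity_update(p, np.zeros(2), params, rng)
        assert np.allclose(out, [0.2, -0.1])

    def test_clamped_at_v_max(self):
        p = make_particle([0.0], [2.7], [0.0])
        params = SwarmParams(delta=1.0, l1=0.0, l2=0.0, v_max=1.0, n_dims=1)
        out = pso_velocity_update(p, np.zeros(1), params, PinnedRng(0.5))
        assert out[0] == 1.0

    def test_pinned_random_evaluation(self):
        """delta=0.5, l1=l2=2, pinned uniforms 0.5: hand-evaluated update."""
        p = make_particle([0.0, 0.0], [0.0, 0.0], [1.0, 0.0])
        params = SwarmParams(delta=0.5, l1=2.0, l2=2.0, v_max=10, n_dims=2)
        out = pso_velocity_update(p, np.array([0.0, 1.0]), params, PinnedRng(0.5))
        assert np.allclose(out, [1.0, 1.0])

    def test_printed_form_uses_personal_best_twice(self):
        p = make_particle([0.0, 0.0], [0.0, 0.0], [1.0, 0.0])
        params = SwarmParams(delta=0.5, l1=2.0, l2=2.0, v_max=10, n_dims=2)
        out = pso_velocity_update(
            p, np.array([0.0, 1.0]), params, PinnedRng(0.5), printed_form=True
        )
        assert np.allclose(out, [2.0, 0.0])

    def test_dimension_mismatch_rejected(self, rng):
        p = make_particle([0.0, 0.0], [0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            pso_velocity_update(p, np.zeros(3), SwarmParams(n_dims=2), rng)


class TestPsoStep:
    def test_straight_line_motion_without_learning_terms(self, rng):
        """l1=l2=0, delta=1: C(t) = C(0) + t*F(0) exactly."""
        params = SwarmParams(delta=1.0, l1=0.0, l2=0.0, v_max=100.0,
                             n_particles=5, n_dims=3)
        state = init_swarm(params, lambda pos: 0.0, np.random.default_rng(0))
        c0 = [p.position.copy() for p in state.particles]
        f0 = [p.velocity.copy() for p in state.particles]
        for t in range(1, 6):
            state = pso_step(state, lambda pos: 0.0, params, rng)
            for i, p in enumerate(state.particles):
                assert np.allclose(p.position, c0[i] + t * f0[i], atol=1e-12)

    def test_gbest_fitness_monotone(self, rng):
        params = SwarmParams(n_particles=10, n_dims=2)
        fitness = lambda pos: -float((pos**2).sum())
        state = init_swarm(params, fitness, np.random.default_rng(1))
        prev = state.gbest_fitness
        for _ in range(20):
            state = pso_step(state, fitness, params, rng)
            assert state.gbest_fitness >= prev
            prev = state.gbest_fitness

    def test_sphere_optimum_found_and_beats_random_search(self):
        """1-D sphere: the swarm localises the optimum; random search with the
        same evaluation budget does clearly worse."""
        fitness = lambda pos: -float(pos[0] ** 2)
        params = SwarmParams(delta=0.7, l1=1.5, l2=1.5, v_max=2.0,
                             n_particles=20, n_dims=1)
        gen = np.random.default_rng(7)
        state = init_swarm(params, fitness, gen, position_low=-5, position_high=5)
        for _ in range(50):
            state = pso_step(state, fitness, params, gen)
        assert abs(state.gbest_position[0]) < 0.1
        draws = np.random.default_rng(7).uniform(-5, 5, size=20 * 51)
        best_random = max(-d**2 for d in draws)
        assert state.gbest_fitness >= best_random

    def test_non_finite_fitness_rejected(self, rng):
        params = SwarmParams(n_particles=2, n_dims=1)
        state = init_swarm(params, lambda pos: 0.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            pso_step(state, lambda pos: float("nan"), params, rng)


class TestAcoProbabilities:
    def test_zero_exponents_give_uniform(self):
        colony = ColonyState(np.array([1.0, 9.0, 4.0, 2.0]), np.ones(4),
                             alpha=0.0, beta=0.0)
        assert np.allclose(aco_selection_probabilities(colony), 0.25)

    def test_direct_evaluation_two_features(self):
        colony = ColonyState(np.array([1.0, 3.0]), np.ones(2), alpha=1.0, beta=1.0)
        assert np.allclose(aco_selection_probabilities(colony), [0.25, 0.75])

    def test_direct_evaluation_with_heuristic_exponent(self):
        colony = ColonyState(np.array([2.0, 2.0, 4.0]), np.array([1.0, 2.0, 1.0]),
                             alpha=1.0, beta=2.0)
        assert np.allclose(
            aco_selection_probabilities(colony), [2 / 14, 8 / 14, 4 / 14]
        )

    def test_simplex_and_monotonicity_random_draws(self, rng):
        for _ in range(200):
            d = int(rng.integers(2, 10))
            mu = rng.uniform(0.1, 5.0, d)
            phi = rng.uniform(0.0, 5.0, d)
            alpha, beta = rng.uniform(0, 3), rng.uniform(0, 3)
            colony = ColonyState(mu, phi, alpha=alpha, beta=beta)
            probs = aco_selection_probabilities(colony)
            assert probs.min() >= 0
            assert abs(probs.sum() - 1.0) < 1e-12
            if alpha > 0 and phi[0] > 0:
                bumped = ColonyState(mu * np.where(np.arange(d) == 0, 2.0, 1.0),
                                     phi, alpha=alpha, beta=beta)
                assert aco_selection_probabilities(bumped)[0] > probs[0]

    def test_all_zero_weights_rejected(self):
        colony = ColonyState(np.ones(3), np.zeros(3), alpha=1.0, beta=1.0)
        with pytest.raises(ValueError):
            aco_selection_probabilities(colony)


class TestAcoConstructSolution:
    def test_degenerate_distribution(self, rng):
        for _ in range(10):
            assert aco_construct_solution(np.array([1.0, 0.0, 0.0]), 1, rng) == [0]

    def test_k_equals_d_returns_full_set(self, rng):
        out = aco_construct_solution(np.array([0.2, 0.5, 0.3]), 3, rng)
        assert np.array_equal(out, [0, 1, 2])

    def test_sampling_frequency_matches_probabilities(self):
        gen = np.random.default_rng(0)
        n = 20_000
        hits = sum(
            aco_construct_solution(np.array([0.25, 0.75]), 1, gen)[0] == 1
            for _ in range(n)
        )
        tol = 3 * np.sqrt(0.25 * 0.75 / n)
        assert abs(hits / n - 0.75) < tol

    def test_more_than_nonzero_rejected(self, rng):
        with pytest.raises(ValueError):
            aco_construct_solution(np.array([1.0, 0.0]), 2, rng)


class TestPheromoneUpdate:
    def test_no_evaporation_no_deposit_leaves_mu(self):
        colony = ColonyState(np.array([2.0, 3.0]), np.ones(2), rho=1e-12)
        aco_update_pheromone(colony, [np.array([0])], [0.0])
        assert np.allclose(colony.pheromone, [2.0, 3.0])

    def test_evaporation_plus_elitist_deposit(self):
        colony = ColonyState(np.array([1.0, 1.0]), np.ones(2), rho=0.5)
        aco_update_pheromone(colony, [np.array([0])], [1.0])
        assert np.allclose(colony.pheromone, [1.5, 0.5])

    def test_floor_clamp(self):
        colony = ColonyState(np.array([1.0, 1.0]), np.ones(2), rho=0.9)
        for _ in range(50):
            aco_update_pheromone(colony, [np.array([0])], [0.5])
        assert colony.pheromone.min() >= 1e-3

    def test_empty_solutions_rejected(self):
        colony = ColonyState(np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            aco_update_pheromone(colony, [], [])


class TestFinalBest:
    def test_probabilities_from_fitnesses(self):
        h = HybridState(fitness_best=3.0, fitness_gbest=1.0)
        out = hybrid_select_finalbest(h, np.array([1]), np.array([2]), PinnedRng(0.9))
        assert h.p_best == 0.75 and h.p_gbest == 0.25
        assert h.p_best + h.p_gbest == 1.0
        assert out == [2]  # r=0.9 >= 0.75 -> PSO gbest

    def test_r_below_p_best_returns_aco_side(self):
        h = HybridState(fitness_best=3.0, fitness_gbest=1.0)
        out = hybrid_select_finalbest(h, np.array([1]), np.array([2]), PinnedRng(0.6))
        assert out == [1]

    def test_equal_fitnesses_split_evenly(self, rng):
        h = HybridState(fitness_best=2.0, fitness_gbest=2.0)
        hybrid_select_finalbest(h, np.array([0]), np.array([1]), rng)
        assert h.p_best == h.p_gbest == 0.5

    def test_nonpositive_fitness_rejected(self, rng):
        h = HybridState(fitness_best=0.0, fitness_gbest=-1.0)
        with pytest.raises(ValueError):
            hybrid_select_finalbest(h, np.array([0]), np.array([1]), rng)

    def test_choice_frequency_matches_p_best(self):
        gen = np.random.default_rng(3)
        h = HybridState(fitness_best=3.0, fitness_gbest=1.0)
        n = 20_000
        hits = sum(
            hybrid_select_finalbest(h, np.array([1]), np.array([2]), gen)[0] == 1
            for _ in range(n)
        )
        tol = 3 * np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < tol


class TestFeatureFitness:
    def test_informative_beats_noise_feature(self):
        p = generate_feature_selection_problem(120, 10, 1, 3.0, seed=4)
        informative = int(p.support_true[0])
        noise = next(j for j in range(10) if j != informative)
        f_inf = feature_fitness(p.X, p.y, np.array([informative]))
        f_noise = feature_fitness(p.X, p.y, np.array([noise]))
        assert f_inf > f_noise

    def test_random_labels_give_chance_level(self):
        gen = np.random.default_rng(0)
        X = gen.standard_normal((200, 10))
        y = gen.integers(0, 2, 200)
        fit = feature_fitness(X, y, np.arange(10))
        assert abs(fit - 0.5) < 0.15

    def test_bounds(self, rng):
        p = generate_feature_selection_problem(60, 8, 2, 1.0, seed=5)
        for lam in (0.0, 0.3):
            fit = feature_fitness(p.X, p.y, np.arange(8), sparsity_weight=lam)
            assert -lam <= fit <= 1.0

    def test_empty_subset_rejected(self):
        p = generate_feature_selection_problem(20, 4, 1, 1.0, seed=0)
        with pytest.raises(ValueError):
            feature_fitness(p.X, p.y, np.array([], dtype=int))

    def test_matches_sklearn_nearest_centroid_per_fold(self):
        """Dual route: the vectorised CV accuracy equals sklearn's NearestCentroid
        evaluated on the same folds."""
        p = generate_feature_selection_problem(60, 5, 2, 1.0, seed=8)
        folds = _stratified_folds(p.y, 3, np.random.default_rng(0))
        ours = _nearest_centroid_accuracy(p.X, p.y, folds)
        accs = []
        for test in folds:
            train = np.setdiff1d(np.arange(60), test)
            clf = NearestCentroid().fit(p.X[train], p.y[train])
            accs.append(np.mean(clf.predict(p.X[test]) == p.y[test]))
        assert ours == pytest.approx(np.mean(accs), abs=1e-12)


class TestRunPsaco:
    def test_single_feature_problem(self):
        p = generate_feature_selection_problem(40, 1, 1, 1.0, seed=0)
        sel, history = run_psaco_feature_selection(p.X, p.y, PsacoConfig(k=1, seed=0))
        assert np.array_equal(sel, [0])

    def test_seed_determinism(self):
        p = generate_feature_selection_problem(80, 12, 3, 2.0, seed=2)
        cfg = PsacoConfig(k=3, n_particles=8, n_iterations=8, seed=5)
        a = run_psaco_feature_selection(p.X, p.y, cfg)
        b = run_psaco_feature_selection(p.X, p.y, cfg)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_history_non_decreasing_with_elitism(self):
        p = generate_feature_selection_problem(80, 12, 3, 2.0, seed=3)
        cfg = PsacoConfig(k=3, n_particles=8, n_iterations=12, seed=1)
        _, history = run_psaco_feature_selection(p.X, p.y, cfg)
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_invalid_iterations_rejected(self):
        p = generate_feature_selection_problem(40, 4, 1, 1.0, seed=0)
        with pytest.raises(ValueError):
            run_psaco_feature_selection(p.X, p.y, PsacoConfig(k=2, n_iterations=0))

    def test_velocities_stay_clamped_during_run(self, rng):
        params = SwarmParams(delta=0.9, l1=2.0, l2=2.0, v_max=1.5,
                             n_particles=10, n_dims=4)
        fitness = lambda pos: -float((pos**2).sum())
        state = init_swarm(params, fitness, np.random.default_rng(0))
        for _ in range(25):
            state = pso_step(state, fitness, params, rng)
            for p in state.particles:
                assert np.all(np.abs(p.velocity) <= params.v_max + 1e-15)


def test_decode_position_ties_prefer_lowest_index():
    assert np.array_equal(decode_position(np.array([0.5, 0.5, 0.5, 0.1]), 2), [0, 1])


def test_fisher_scores_rank_informative_features():
    p = generate_feature_selection_problem(150, 20, 4, 2.0, seed=6)
    scores = fisher_scores(p.X, p.y)
    top4 = np.argsort(-scores)[:4]
    assert set(top4) == set(p.support_true.tolist())
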