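"""Hybrid particle-swarm / ant-colony wavelength (feature-subset) selection.

Two metaheuristics run side by side on the same wrapper fitness:

* a particle swarm in continuous R^d — velocity update
  ``F' = delta*F + l1*r1*(O - C) + l2*r2*(P_gbest - C)`` with per-dimension
  uniform draws and a hard clamp at ``|F'| <= v_max``; a particle's position
  decodes to the subset of its k largest components;
* an ant colony over feature indices — selection probability
  ``P_j = mu_j^alpha * phi_j^beta / sum_i mu_i^alpha * phi_i^beta`` with
  pheromone mu (evaporation-plus-elitist-deposit update) and a per-feature
  heuristic phi (absolute Fisher score).

Each iteration the two champions are recombined into ``FinalBest``: the ACO
best is chosen with probability ``f_best / (f_best + f_gbest)``, otherwise
the PSO gbest.  FinalBest is injected back as the swarm's global best and as
the colony's pheromone-deposit target, coupling exploitation across the two
populations.  With elitism (default) the FinalBest fitness history is
non-decreasing.

The wrapper fitness is stratified cross-validated nearest-centroid accuracy
on the candidate columns minus a sparsity penalty ``lambda * |subset| / d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Particle",
    "SwarmParams",
    "SwarmState",
    "ColonyState",
    "HybridState",
    "PsacoConfig",
    "pso_velocity_update",
    "pso_step",
    "aco_selection_probabilities",
    "aco_construct_solution",
    "aco_update_pheromone",
    "hybrid_select_finalbest",
    "fisher_scores",
    "feature_fitness",
    "decode_position",
    "run_psaco_feature_selection",
    "random_subset_baseline",
]

PHEROMONE_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class Particle:
    """One swarm member: position C, velocity F, personal best O."""

    position: np.ndarray
    velocity: np.ndarray
    personal_best: np.ndarray
    personal_best_fitness: float


@dataclass(frozen=True)
class SwarmParams:
    """Inertia delta, learning factors l1/l2, velocity clamp v_max, sizes."""

    delta: float = 0.9
    l1: float = 2.0
    l2: float = 2.0
    v_max: float = 4.0
    n_particles: int = 20
    n_dims: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must lie in (0, 1]")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("learning factors must be >= 0")
        if self.v_max <= 0:
            raise ValueError("v_max must be > 0")
        if self.n_particles < 1 or self.n_dims < 1:
            raise ValueError("n_particles and n_dims must be >= 1")


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0


@dataclass
class ColonyState:
    """Pheromone mu (> 0), heuristic phi (>= 0), exponents alpha/beta, evaporation rho."""

    pheromone: np.ndarray
    heuristic: np.ndarray
    alpha: float = 1.0
    beta: float = 2.0
    rho: float = 0.1
    best_solution: np.ndarray | None = None
    best_fitness: float = -np.inf

    def __post_init__(self) -> None:
        self.pheromone = np.asarray(self.pheromone, dtype=float)
        self.heuristic = np.asarray(self.heuristic, dtype=float)
        if self.pheromone.shape != self.heuristic.shape:
            raise ValueError("pheromone and heuristic must have equal length")
        if np.any(self.pheromone <= 0):
            raise ValueError("pheromone must be strictly positive")
        if np.any(self.heuristic < 0):
            raise ValueError("heuristic must be non-negative")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")


@dataclass
class HybridState:
    """FinalBest bookkeeping: the two champion fitnesses and selection probabilities."""

    fitness_best: float = -np.inf   # ACO side
    fitness_gbest: float = -np.inf  # PSO side
    p_best: float = float("nan")
    p_gbest: float = float("nan")
    final_best: np.ndarray | None = None
    final_best_fitness: float = -np.inf
    r: float = float("nan")


@dataclass(frozen=True)
class PsacoConfig:
    """Hyperparameters of the full hybrid selection run."""

    k: int = 5
    n_particles: int = 20
    n_iterations: int = 30
    l1: float = 2.0
    l2: float = 2.0
    v_max: float = 4.0
    delta_start: float = 0.9
    delta_end: float = 0.4
    alpha: float = 1.0
    beta: float = 2.0
    rho: float = 0.1
    sparsity_weight: float = 0.0
    cv_folds: int = 3
    elitism: bool = True
    printed_velocity_form: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# Particle swarm
# ---------------------------------------------------------------------------

def pso_velocity_update(
    p: Particle,
    gbest: np.ndarray,
    params: SwarmParams,
    rng: np.random.Generator,
    printed_form: bool = False,
) -> np.ndarray:
    """New velocity, clamped element-wise to [-v_max, v_max].

    ``printed_form=True`` selects the variant in which BOTH stochastic terms
    pull toward the personal best (no social term); the default is the
    standard form pulling toward the personal best and the global best.
    """
    gbest = np.asarray(gbest, dtype=float)
    if gbest.shape != p.position.shape:
        raise ValueError("dimension mismatch between particle and gbest")
    r1 = rng.uniform(size=p.position.shape)
    r2 = rng.uniform(size=p.position.shape)
    cognitive = params.l1 * r1 * (p.personal_best - p.position)
    social_target = p.personal_best if printed_form else gbest
    social = params.l2 * r2 * (social_target - p.position)
    new_v = params.delta * p.velocity + cognitive + social
    return np.clip(new_v, -params.v_max, params.v_max)


def init_swarm(
    params: SwarmParams,
    fitness_fn,
    rng: np.random.Generator,
    position_low: float = 0.0,
    position_high: float = 1.0,
) -> SwarmState:
    """Uniform positions in [low, high]^d, small uniform velocities."""
    particles = []
    for _ in range(params.n_particles):
        pos = rng.uniform(position_low, position_high, size=params.n_dims)
        vel = rng.uniform(-params.v_max / 4.0, params.v_max / 4.0, size=params.n_dims)
        fit = float(fitness_fn(pos))
        particles.append(Particle(pos, vel, pos.copy(), fit))
    best = max(range(len(particles)), key=lambda i: particles[i].personal_best_fitness)
    return SwarmState(
        particles=particles,
        gbest_position=particles[best].personal_best.copy(),
        gbest_fitness=particles[best].personal_best_fitness,
    )


def pso_step(
    state: SwarmState,
    fitness_fn,
    params: SwarmParams,
    rng: np.random.Generator,
    printed_form: bool = False,
) -> SwarmState:
    """One synchronous swarm iteration; gbest fitness is non-decreasing."""
    for p in state.particles:
        p.velocity = pso_velocity_update(p, state.gbest_position, params, rng, printed_form)
        p.position = p.position + p.velocity
        fit = float(fitness_fn(p.position))
        if not np.isfinite(fit):
            raise ValueError("fitness_fn returned a non-finite value")
        if fit > p.personal_best_fitness:
            p.personal_best = p.position.copy()
            p.personal_best_fitness = fit
        if fit > state.gbest_fitness:
            state.gbest_position = p.position.copy()
            state.gbest_fitness = fit
    state.iteration += 1
    return state


# ---------------------------------------------------------------------------
# Ant colony
# ---------------------------------------------------------------------------

def aco_selection_probabilities(colony: ColonyState) -> np.ndarray:
    """Per-feature selection probabilities mu^alpha * phi^beta, normalised."""
    weights = colony.pheromone**colony.alpha * colony.heuristic**colony.beta
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all selection weights vanish; probabilities undefined")
    return weights / total


def aco_construct_solution(
    probs: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample k distinct feature indices without replacement, proportional to probs."""
    probs = np.asarray(probs, dtype=float)
    d = probs.size
    if not (1 <= k <= d):
        raise ValueError("need 1 <= k <= d")
    if np.count_nonzero(probs) < k:
        raise ValueError("fewer nonzero-probability features than k")
    remaining = probs.copy()
    chosen: list[int] = []
    for _ in range(k):
        p = remaining / remaining.sum()
        idx = int(rng.choice(d, p=p))
        chosen.append(idx)
        remaining[idx] = 0.0
    return np.sort(np.asarray(chosen, dtype=int))


def aco_update_pheromone(
    colony: ColonyState,
    solutions: list[np.ndarray],
    fitnesses: list[float],
    deposit_solution: np.ndarray | None = None,
    deposit_fitness: float | None = None,
) -> ColonyState:
    """Evaporate then deposit on the elite solution's features.

    ``mu <- (1 - rho) * mu``; the iteration-best solution (or an explicitly
    supplied elite, e.g. FinalBest) receives its fitness as deposit; mu is
    floor-clamped at ``PHEROMONE_FLOOR``.  Also refreshes the colony's
    best-so-far bookkeeping from the iteration's solutions.
    """
    if len(solutions) == 0:
        raise ValueError("empty solution list")
    if len(solutions) != len(fitnesses):
        raise ValueError("solutions and fitnesses must have equal length")
    best_i = int(np.argmax(fitnesses))
    if fitnesses[best_i] > colony.best_fitness:
        colony.best_fitness = float(fitnesses[best_i])
        colony.best_solution = np.asarray(solutions[best_i], dtype=int).copy()

    if deposit_solution is None:
        deposit_solution = solutions[best_i]
        deposit_fitness = float(fitnesses[best_i])
    colony.pheromone = (1.0 - colony.rho) * colony.pheromone
    colony.pheromone[np.asarray(deposit_solution, dtype=int)] += float(deposit_fitness)
    np.maximum(colony.pheromone, PHEROMONE_FLOOR, out=colony.pheromone)
    return colony


# ---------------------------------------------------------------------------
# Hybrid recombination (FinalBest)
# ---------------------------------------------------------------------------

def hybrid_select_finalbest(
    h: HybridState,
    best: np.ndarray,
    gbest: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Choose the ACO best with probability f_best/(f_best+f_gbest), else PSO gbest.

    Fills ``h.p_best``, ``h.p_gbest``, ``h.r`` and ``h.final_best``; requires
    both fitnesses positive so the probabilities are well defined.
    """
    fb, fg = h.fitness_best, h.fitness_gbest
    if not (fb > 0 and fg > 0):
        raise ValueError("FinalBest probabilities need positive fitnesses on both sides")
    h.p_best = fb / (fb + fg)
    h.p_gbest = 1.0 - h.p_best  # exact complement of fg/(fb+fg)
    h.r = float(rng.uniform())
    if h.r < h.p_best:
        h.final_best = np.asarray(best).copy()
        h.final_best_fitness = fb
    else:
        h.final_best = np.asarray(gbest).copy()
        h.final_best_fitness = fg
    return h.final_best


# ---------------------------------------------------------------------------
# Wrapper fitness
# ---------------------------------------------------------------------------

def fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute Fisher score per column: |mean1 - mean0| / pooled SD."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    x0, x1 = X[y == 0], X[y == 1]
    num = np.abs(x1.mean(axis=0) - x0.mean(axis=0))
    pooled = np.sqrt(0.5 * (x0.var(axis=0, ddof=1) + x1.var(axis=0, ddof=1)))
    return num / (pooled + 1e-12)


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled per-class round-robin fold assignment (test-index lists)."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def _nearest_centroid_accuracy(
    X: np.ndarray, y: np.ndarray, folds: list[np.ndarray]
) -> float:
    """Mean CV accuracy of a Euclidean nearest-centroid rule (tie -> class 0)."""
    n = y.size
    classes = np.unique(y)
    accs = []
    all_idx = np.arange(n)
    for test in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test] = False
        train = all_idx[train_mask]
        centroids = np.stack([X[train][y[train] == c].mean(axis=0) for c in classes])
        d2 = ((X[test][:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        pred = classes[np.argmin(d2, axis=1)]
        accs.append(float(np.mean(pred == y[test])))
    return float(np.mean(accs))


def feature_fitness(
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray,
    cv_folds: int = 3,
    sparsity_weight: float = 0.0,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Stratified CV nearest-centroid accuracy on X[:, subset] minus sparsity penalty.

    Deterministic given the rng seed (folds are the only randomness).
    Bounded in ``[-sparsity_weight, 1]``.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    folds = _stratified_folds(y, cv_folds, rng)
    acc = _nearest_centroid_accuracy(X[:, subset], y, folds)
    return acc - sparsity_weight * subset.size / X.shape[1]


def decode_position(position: np.ndarray, k: int) -> np.ndarray:
    """Subset of the k largest position components; ties favour the lowest index."""
    position = np.asarray(position, dtype=float)
    order = np.argsort(-position, kind="stable")
    return np.sort(order[:k])


def _encode_subset(subset: np.ndarray, d: int) -> np.ndarray:
    """Indicator-vector position whose decode returns the subset."""
    pos = np.zeros(d)
    pos[np.asarray(subset, dtype=int)] = 1.0
    return pos


# ---------------------------------------------------------------------------
# Full hybrid run
# ---------------------------------------------------------------------------

def run_psaco_feature_selection(
    X: np.ndarray,
    y: np.ndarray,
    config: PsacoConfig,
) -> tuple[np.ndarray, list[float]]:
    """Run the coupled swarm + colony for ``config.n_iterations`` iterations.

    Returns the selected feature index set (the best FinalBest seen) and the
    per-iteration FinalBest-fitness history, which is non-decreasing when
    ``config.elitism`` is on.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if config.n_iterations < 1:
        raise ValueError("iterations must be >= 1")
    k = min(config.k, d)
    if d == 1:
        return np.array([0]), [
            feature_fitness(X, y, np.array([0]), config.cv_folds,
                            config.sparsity_weight, config.seed)
        ]

    rng = np.random.default_rng(config.seed)
    fold_seed = int(rng.integers(2**31))

    def fit_subset(subset: np.ndarray) -> float:
        return feature_fitness(
            X, y, subset, config.cv_folds, config.sparsity_weight, fold_seed
        )

    def fit_position(pos: np.ndarray) -> float:
        return fit_subset(decode_position(pos, k))

    swarm_params = SwarmParams(
        delta=config.delta_start,
        l1=config.l1,
        l2=config.l2,
        v_max=config.v_max,
        n_particles=config.n_particles,
        n_dims=d,
    )
    swarm = init_swarm(swarm_params, fit_position, rng)

    colony = ColonyState(
        pheromone=np.ones(d),
        heuristic=fisher_scores(X, y),
        alpha=config.alpha,
        beta=config.beta,
        rho=config.rho,
    )

    hybrid = HybridState()
    history: list[float] = []
    elite_solution: np.ndarray | None = None
    elite_fitness = -np.inf

    for t in range(config.n_iterations):
        # linear inertia schedule delta_start -> delta_end
        frac = t / max(config.n_iterations - 1, 1)
        delta_t = config.delta_start + frac * (config.delta_end - config.delta_start)
        params_t = SwarmParams(
            delta=delta_t, l1=config.l1, l2=config.l2, v_max=config.v_max,
            n_particles=config.n_particles, n_dims=d,
        )
        swarm = pso_step(swarm, fit_position, params_t, rng, config.printed_velocity_form)

        probs = aco_selection_probabilities(colony)
        solutions = [aco_construct_solution(probs, k, rng) for _ in range(config.n_particles)]
        fitnesses = [fit_subset(s) for s in solutions]

        # FinalBest between the two champions
        hybrid.fitness_best = max(colony.best_fitness, float(np.max(fitnesses)))
        hybrid.fitness_gbest = swarm.gbest_fitness
        aco_champion = solutions[int(np.argmax(fitnesses))]
        if colony.best_fitness > np.max(fitnesses) and colony.best_solution is not None:
            aco_champion = colony.best_solution
        pso_champion = decode_position(swarm.gbest_position, k)
        if hybrid.fitness_best > 0 and hybrid.fitness_gbest > 0:
            final = hybrid_select_finalbest(hybrid, aco_champion, pso_champion, rng)
            final_fit = hybrid.final_best_fitness
        else:  # degenerate fitnesses: fall back to the better champion
            if hybrid.fitness_best >= hybrid.fitness_gbest:
                final, final_fit = aco_champion, hybrid.fitness_best
            else:
                final, final_fit = pso_champion, hybrid.fitness_gbest

        if final_fit > elite_fitness or elite_solution is None:
            elite_fitness = float(final_fit)
            elite_solution = np.asarray(final, dtype=int).copy()
        history.append(elite_fitness if config.elitism else float(final_fit))

        # feedback: FinalBest becomes the swarm's gbest and the colony's deposit target
        inject = elite_solution if config.elitism else np.asarray(final, dtype=int)
        inject_fit = elite_fitness if config.elitism else float(final_fit)
        if inject_fit >= swarm.gbest_fitness:
            swarm.gbest_position = _encode_subset(inject, d)
            swarm.gbest_fitness = inject_fit
        aco_update_pheromone(colony, solutions, fitnesses,
                             deposit_solution=inject,
                             deposit_fitness=max(inject_fit, 0.0))

    assert elite_solution is not None
    return elite_solution, history


def random_subset_baseline(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    n_evaluations: int,
    cv_folds: int = 3,
    sparsity_weight: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Best of ``n_evaluations`` uniformly random k-subsets under the same fitness."""
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))
    best_subset, best_fit = None, -np.inf
    for _ in range(n_evaluations):
        subset = np.sort(rng.choice(d, size=min(k, d), replace=False))
        fit = feature_fitness(X, y, subset, cv_folds, sparsity_weight, fold_seed)
        if fit > best_fit:
            best_subset, best_fit = subset, fit
    return best_subset, float(best_fit)
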