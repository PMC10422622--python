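"""Mud Ring Optimization Algorithm (MROA): a bounded continuous minimizer.

MROA mimics bottlenose-dolphin foraging.  A population of agents alternates
between an echolocation *exploration* phase — a velocity step (optionally a
spiral around a randomly chosen agent) — and a mud-ring *exploitation*
phase that spirals around the best solution found so far:

    a(t) = 2·(1 − t/T)            linear 2 → 0 decay over T iterations
    K    = 2·a·r − a              r ~ U(0,1), so K ∈ [−a, a]
    C    = 2·r
    A    = |C·D* − D|             elementwise distance to the reference D*
    D'   = D*·sin(2πl) − K·A      l ~ U(−1, 1)

|K| ≥ 1 selects exploration, |K| < 1 exploitation.  Positions are clamped
to the search box after every move.  The fitness used for classifier
tuning is the percent classification error on a validation split.

Random-draw order (fixed, so a trace can be replayed by an independent
oracle): initial positions (N×d), initial velocities (N×d); then per
iteration, per agent: r; then either a fresh velocity (d draws, "velocity"
mode) or an agent index plus l ("random_agent" mode) when exploring, or a
single l when exploiting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Agent:
    position: np.ndarray
    velocity: np.ndarray
    fitness: float = np.inf


@dataclass
class MROAConfig:
    """Run parameters: population N, iteration budget, box and velocity bounds."""

    n_agents: int = 20
    max_iter: int = 100
    lower: np.ndarray | float = -1.0
    upper: np.ndarray | float = 1.0
    v_min: np.ndarray | float = -0.1
    v_max: np.ndarray | float = 0.1
    seed: int = 0
    explore_mode: str = "velocity"  # or "random_agent"

    def __post_init__(self):
        if self.n_agents < 2:
            raise ValueError("population size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def bounds(self, d: int):
        lo = np.broadcast_to(np.asarray(self.lower, dtype=float), (d,)).copy()
        hi = np.broadcast_to(np.asarray(self.upper, dtype=float), (d,)).copy()
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be below upper bounds")
        return lo, hi

    def v_bounds(self, d: int):
        vlo = np.broadcast_to(np.asarray(self.v_min, dtype=float), (d,)).copy()
        vhi = np.broadcast_to(np.asarray(self.v_max, dtype=float), (d,)).copy()
        if np.any(vlo > vhi):
            raise ValueError("v_min must not exceed v_max")
        return vlo, vhi


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness after each iteration (incl. init)
    n_evaluations: int


def coeff_a(t: int, max_iter: int) -> float:
    """Linear decay a = 2·(1 − t/max_iter), from 2 at t=0 to 0 at t=max_iter."""
    if not 0 <= t <= max_iter:
        raise ValueError("iteration index out of range")
    return 2.0 * (1.0 - t / max_iter)


def coeff_K(a: float, r: float) -> float:
    """K = 2·a·r − a, a value in [−a, a] for r in [0, 1]."""
    return 2.0 * a * r - a


def coeff_C(r: float) -> float:
    """C = 2·r, a value in [0, 2]."""
    return 2.0 * r


def _clamp(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.clip(x, lo, hi)


def explore_move(agent: Agent, config: MROAConfig, rng) -> np.ndarray:
    """Echolocation step: redraw the velocity uniformly in [Vmin, Vmax] and
    advance the position by it, clamped to the box."""
    d = agent.position.shape[0]
    vlo, vhi = config.v_bounds(d)
    lo, hi = config.bounds(d)
    agent.velocity = rng.uniform(vlo, vhi)
    return _clamp(agent.position + agent.velocity, lo, hi)


def encircle_move(position: np.ndarray, reference: np.ndarray, K: float,
                  C: float, l: float, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Mud-ring spiral: A = |C·ref − pos|; new = ref·sin(2πl) − K·A, clamped."""
    A = np.abs(C * reference - position)
    new = reference * np.sin(2.0 * np.pi * l) - K * A
    return _clamp(new, lo, hi)


def _safe_fitness(fn, x: np.ndarray) -> float:
    value = float(fn(x))
    if not np.isfinite(value):
        logger.warning("non-finite fitness %r at %s; treating as +inf", value, x)
        return np.inf
    return value


def optimize(fitness_fn, d: int, config: MROAConfig) -> OptimizationResult:
    """Run MROA on a d-dimensional box; returns the best-ever solution.

    Exactly N·(max_iter + 1) fitness evaluations are performed (initial
    population plus one per agent per iteration), and the best-so-far
    history is non-increasing by construction.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds(d)
    vlo, vhi = config.v_bounds(d)

    positions = rng.uniform(lo, hi, size=(config.n_agents, d))
    velocities = rng.uniform(vlo, vhi, size=(config.n_agents, d))
    agents = [Agent(p, v) for p, v in zip(positions, velocities)]
    for ag in agents:
        ag.fitness = _safe_fitness(fitness_fn, ag.position)
    n_evals = config.n_agents

    best_idx = int(np.argmin([ag.fitness for ag in agents]))
    best_pos = agents[best_idx].position.copy()
    best_fit = agents[best_idx].fitness
    history = [best_fit]

    for t in range(1, config.max_iter + 1):
        a = coeff_a(t, config.max_iter)
        for i, ag in enumerate(agents):
            r = rng.uniform()
            K = coeff_K(a, r)
            C = coeff_C(r)
            if abs(K) >= 1.0:
                if config.explore_mode == "random_agent":
                    j = int(rng.integers(config.n_agents))
                    l = rng.uniform(-1.0, 1.0)
                    new_pos = encircle_move(ag.position, agents[j].position,
                                            K, C, l, lo, hi)
                else:
                    new_pos = explore_move(ag, config, rng)
            else:
                l = rng.uniform(-1.0, 1.0)
                new_pos = encircle_move(ag.position, best_pos, K, C, l, lo, hi)
            ag.position = new_pos
            ag.fitness = _safe_fitness(fitness_fn, new_pos)
            n_evals += 1
            if ag.fitness < best_fit:
                best_fit = ag.fitness
                best_pos = ag.position.copy()
        history.append(best_fit)

    return OptimizationResult(best_position=best_pos, best_fitness=best_fit,
                              history=np.array(history), n_evaluations=n_evals)


def classification_error_rate(y_true, y_pred) -> float:
    """Percent misclassified: 100 · (#wrong / #total)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean(y_true != y_pred))


# ---------------------------------------------------------------------------
# hyperparameter tuning of the stacked-autoencoder classifier

@dataclass
class HyperparameterSpace:
    """Decodes a 6-dimensional position into classifier hyperparameters.

    dim 1: log10 learning rate, uniform over [−4, −1] (lr in [1e-4, 0.1]);
    dim 2: layer count, rounded into {1, 2, 3};
    dims 3–5: per-layer hidden sizes, rounded into [4, 128] (dims beyond
    the layer count are ignored);
    dim 6: dropout probability in [0, 0.8].
    """

    log_lr_bounds: tuple = (-4.0, -1.0)
    layer_bounds: tuple = (1, 3)
    size_bounds: tuple = (4, 128)
    dropout_bounds: tuple = (0.0, 0.8)

    @property
    def d(self) -> int:
        return 6

    def box(self):
        lo = np.array([self.log_lr_bounds[0], self.layer_bounds[0],
                       self.size_bounds[0], self.size_bounds[0],
                       self.size_bounds[0], self.dropout_bounds[0]], dtype=float)
        hi = np.array([self.log_lr_bounds[1], self.layer_bounds[1],
                       self.size_bounds[1], self.size_bounds[1],
                       self.size_bounds[1], self.dropout_bounds[1]], dtype=float)
        return lo, hi

    def decode(self, position: np.ndarray) -> dict:
        p = np.asarray(position, dtype=float)
        n_layers = int(np.clip(round(p[1]), *self.layer_bounds))
        sizes = [int(np.clip(round(p[2 + i]), *self.size_bounds))
                 for i in range(n_layers)]
        return {
            "learning_rate": float(10.0 ** p[0]),
            "hidden_sizes": sizes,
            "dropout": float(np.clip(p[5], *self.dropout_bounds)),
        }


def tune_saetm(
    train_features: np.ndarray,
    train_labels,
    val_features: np.ndarray,
    val_labels,
    space: HyperparameterSpace | None = None,
    mroa_config: MROAConfig | None = None,
    train_config=None,
    classes: list | None = None,
):
    """Tune the stacked-autoencoder classifier by minimising validation
    classification error with MROA.

    The inner training seed is held fixed so the fitness is a deterministic
    function of the search position.  Returns (best_hyperparameters,
    refitted stack, OptimizationResult).
    """
    from . import saetm as _saetm

    if space is None:
        space = HyperparameterSpace()
    if train_config is None:
        train_config = _saetm.TrainConfig()
    if classes is None:
        classes = sorted(set(np.asarray(train_labels).tolist()))
    lo, hi = space.box()
    if mroa_config is None:
        mroa_config = MROAConfig(n_agents=6, max_iter=5, lower=lo, upper=hi,
                                 v_min=-0.1 * (hi - lo), v_max=0.1 * (hi - lo))
    else:
        mroa_config = MROAConfig(
            n_agents=mroa_config.n_agents, max_iter=mroa_config.max_iter,
            lower=lo, upper=hi,
            v_min=-0.1 * (hi - lo), v_max=0.1 * (hi - lo),
            seed=mroa_config.seed, explore_mode=mroa_config.explore_mode,
        )

    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)

    def fit_at(position: np.ndarray):
        hp = space.decode(position)
        cfg = _saetm.TrainConfig(
            learning_rate=hp["learning_rate"], epochs=train_config.epochs,
            batch_size=train_config.batch_size, dropout=hp["dropout"],
            seed=train_config.seed, hidden_activation=train_config.hidden_activation,
            finetune_scope=train_config.finetune_scope,
        )
        return _saetm.fit_classifier(train_features, train_labels,
                                     hp["hidden_sizes"], cfg, classes=classes)

    def fitness(position: np.ndarray) -> float:
        stack = fit_at(position)
        pred = _saetm.predict(stack, val_features)
        return classification_error_rate(val_labels, pred)

    result = optimize(fitness, space.d, mroa_config)
    best_hp = space.decode(result.best_position)
    best_stack = fit_at(result.best_position)
    return best_hp, best_stack, result
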