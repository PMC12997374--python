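"""Wrapper feature selection by binary gravitational search with a
logarithmic-spiral local search.

Agents are binary masks over the original attributes.  Fitness balances
the cross-validated classification error of a classifier trained on the
masked features against the subset size:

    f(mask) = alpha * error(mask) + beta * |mask| / D

Agents attract each other with fitness-derived masses (heavier = fitter);
with probability ``spiral_prob`` an agent instead takes a logarithmic
spiral step around the incumbent best mask, which refines promising
regions and fights premature convergence.  Continuous moves are mapped
back to bits through a stochastic sigmoid transfer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class FSConfig:
    """Search settings.

    Defaults follow the reference setup: 20 agents, 100 iterations,
    fitness weights 0.9/0.1, spiral radius 0.5.  ``g_decay`` is the decay
    exponent of the gravitational constant G(t) = G0 exp(-g_decay t/T).
    ``kbest`` shrinks linearly from all agents to one, the usual GSA
    convention.  Two documented formulation ambiguities are exposed as
    switches: ``velocity_rule`` ("inertia" keeps w(t)·v memory; "random"
    uses a U(0,1) coefficient) and ``sigmoid_on`` ("velocity" feeds the
    transfer with v; "position" with the continuous position).

    ``spiral_binarize`` controls how a spiral move maps back to bits:
    "threshold" (default) treats the spiral position — a geometric
    interpolation inside the unit hypercube — as a Bernoulli probability
    directly, so θ = 0 lands exactly on the incumbent best mask;
    "sigmoid" squashes it through the transfer function first, which
    compresses the move into the [0.5, 0.73] probability band and turns
    the spiral into a bit randomizer (kept for comparison only).
    """

    n_agents: int = 20
    max_iter: int = 100
    g0: float = 100.0
    g_decay: float = 15.0
    w_max: float = 0.9
    w_min: float = 0.4
    alpha: float = 0.9
    beta: float = 0.1
    spiral_prob: float = 0.5
    spiral_b: float = 1.0
    spiral_r: float = 0.5
    eps: float = 1e-10
    velocity_rule: str = "inertia"
    sigmoid_on: str = "velocity"
    spiral_binarize: str = "threshold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("fitness weights must be non-negative")
        if not 0 <= self.spiral_prob <= 1:
            raise ValueError("spiral_prob must lie in [0, 1]")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")
        if self.velocity_rule not in ("inertia", "random"):
            raise ValueError("velocity_rule must be 'inertia' or 'random'")
        if self.sigmoid_on not in ("velocity", "position"):
            raise ValueError("sigmoid_on must be 'velocity' or 'position'")
        if self.spiral_binarize not in ("threshold", "sigmoid"):
            raise ValueError(
                "spiral_binarize must be 'threshold' or 'sigmoid'")


@dataclass
class SwarmState:
    """Positions, velocities, fitness, masses and the incumbent best."""

    positions: np.ndarray  # N x D, {0,1}
    velocities: np.ndarray  # N x D
    fitness: np.ndarray  # N
    masses: np.ndarray  # N, sums to 1
    best_position: np.ndarray  # D, {0,1}
    best_fitness: float
    iteration: int = 0


def fitness(mask: np.ndarray, error_rate: float, cfg: FSConfig) -> float:
    """alpha * error + beta * |selected| / D."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("mask must be non-empty")
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must lie in [0, 1]")
    return cfg.alpha * error_rate + cfg.beta * mask.sum() / mask.size


def update_constants(t: int, cfg: FSConfig) -> tuple[float, float]:
    """G(t) = G0 exp(-decay t/T);  w(t) linear from w_max to w_min."""
    if not 0 <= t <= cfg.max_iter:
        raise ValueError("iteration out of range")
    frac = t / cfg.max_iter if cfg.max_iter > 0 else 0.0
    g = cfg.g0 * np.exp(-cfg.g_decay * frac)
    w = cfg.w_max - (cfg.w_max - cfg.w_min) * frac
    return float(g), float(w)


def compute_masses(f: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Normalized masses m_i = (f_max - f_i)/(f_max - f_min + eps).

    Lower fitness (better subset) means heavier mass.  Equal fitness
    degenerates to a uniform distribution.
    """
    f = np.asarray(f, dtype=float)
    fmax, fmin = f.max(), f.min()
    if fmax == fmin:
        return np.full(f.size, 1.0 / f.size)
    m = (fmax - f) / (fmax - fmin + eps)
    return m / m.sum()


def kbest_count(t: int, cfg: FSConfig) -> int:
    """Linearly shrinking pool of force-exerting agents: N -> 1."""
    if cfg.max_iter <= 1:
        return cfg.n_agents
    frac = min(t, cfg.max_iter - 1) / (cfg.max_iter - 1)
    return max(1, int(round(cfg.n_agents - (cfg.n_agents - 1) * frac)))


def accelerations(state: SwarmState, g: float, kbest: int, cfg: FSConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-dimension accelerations from the kbest heaviest agents.

    The force of j on i is G M_i M_j (x_j - x_i) / (R_ij + eps); dividing
    by M_i for the acceleration cancels M_i analytically, so agents with
    vanishing mass still move.  Pairwise contributions carry independent
    U(0,1) weights, drawn in agent-major order for reproducibility.
    """
    if not 1 <= kbest <= state.positions.shape[0]:
        raise ValueError("kbest out of range")
    X = state.positions.astype(float)
    n, d = X.shape
    order = np.argsort(-state.masses, kind="stable")[:kbest]
    acc = np.zeros((n, d))
    # R_ij for all pairs against the kbest set
    diff = X[order][None, :, :] - X[:, None, :]          # n x k x d
    dist = np.sqrt((diff ** 2).sum(axis=2))              # n x k
    w = rng.random((n, kbest))
    for pos, j in enumerate(order):
        contrib = (g * state.masses[j] / (dist[:, pos] + cfg.eps))[:, None] \
            * diff[:, pos, :]
        contrib[j] = 0.0  # no self-force
        acc += w[:, pos, None] * contrib
    return acc


def sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(v, -500, 500)))


def spiral_step(x: np.ndarray, x_best: np.ndarray, b: float,
                theta: np.ndarray) -> np.ndarray:
    """Logarithmic-spiral move around the incumbent best.

    x + (x_best - x) e^{bθ} cos(2πθ): θ = 0 lands exactly on x_best;
    θ = ±1/4 leaves x unchanged (the cosine vanishes).
    """
    x = np.asarray(x, dtype=float)
    return x + (np.asarray(x_best, dtype=float) - x) \
        * np.exp(b * np.asarray(theta)) * np.cos(2 * np.pi * np.asarray(theta))


def binarize(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """bit = 1 iff sigmoid(v) beats a fresh U(0,1) draw."""
    v = np.asarray(v, dtype=float)
    return (sigmoid(v) > rng.random(v.shape)).astype(np.int8)


def move(state: SwarmState, acc: np.ndarray, w: float, cfg: FSConfig,
         rng: np.random.Generator) -> SwarmState:
    """Velocity/position update with the optional spiral jump.

    v <- w v + a (or U(0,1) v + a under the "random" rule).  Each agent
    then either spirals around the incumbent best with probability
    ``spiral_prob`` — x + (x_best - x) e^{bθ} cos(2πθ), θ ~ r·U(-1,1)
    per dimension — or takes the plain ballistic step x + v.

    Ballistic movers binarize the velocity (or continuous position,
    per ``sigmoid_on``) through the stochastic sigmoid transfer.  Spiral
    movers default to thresholding their continuous position against a
    U(0,1) draw: the position is a geometric interpolation between the
    agent and the best mask inside the unit hypercube, already on
    probability scale, so θ = 0 reproduces the best mask exactly.
    """
    X = state.positions.astype(float)
    n, d = X.shape
    if cfg.velocity_rule == "inertia":
        V = w * state.velocities + acc
    else:
        V = rng.random((n, 1)) * state.velocities + acc

    spiral = rng.random(n) < cfg.spiral_prob
    theta = cfg.spiral_r * rng.uniform(-1.0, 1.0, size=(n, d))
    spiral_pos = spiral_step(X, state.best_position, cfg.spiral_b, theta)
    ballistic_pos = X + V

    cont = np.where(spiral[:, None], spiral_pos, ballistic_pos)
    if cfg.sigmoid_on == "position":
        arg = cont
    else:
        arg = np.where(spiral[:, None], cont, V)
    draws = rng.random((n, d))
    sig_bits = (sigmoid(arg) > draws).astype(np.int8)
    if cfg.spiral_binarize == "threshold":
        thr_bits = (np.clip(cont, 0.0, 1.0) > draws).astype(np.int8)
        new_pos = np.where(spiral[:, None], thr_bits, sig_bits)
    else:
        new_pos = sig_bits
    return SwarmState(
        positions=new_pos, velocities=V, fitness=state.fitness.copy(),
        masses=state.masses.copy(), best_position=state.best_position.copy(),
        best_fitness=state.best_fitness, iteration=state.iteration + 1,
    )


def run_sss_bgsa(evaluator: Callable[[np.ndarray], float], d: int,
                 cfg: FSConfig) -> tuple[np.ndarray, float, np.ndarray]:
    """Full search; returns (best mask, best fitness, best-fitness trace).

    ``evaluator`` maps a non-empty binary mask to a classification error
    in [0, 1]; the all-zero mask is charged the worst error so it can
    never win.  Mask evaluations are memoized.  The trace records the
    incumbent best after every iteration and is non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}

    def evaluate(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            if mask.sum() == 0:
                err = 1.0
            else:
                err = float(evaluator(mask))
            cache[key] = fitness(mask, err, cfg)
        return cache[key]

    X = (rng.random((cfg.n_agents, d)) < 0.5).astype(np.int8)
    state = SwarmState(
        positions=X, velocities=np.zeros((cfg.n_agents, d)),
        fitness=np.full(cfg.n_agents, np.inf),
        masses=np.full(cfg.n_agents, 1.0 / cfg.n_agents),
        best_position=X[0].copy(), best_fitness=np.inf,
    )

    trace = []
    for t in range(cfg.max_iter):
        state.fitness = np.array([evaluate(m) for m in state.positions])
        i_best = int(np.argmin(state.fitness))
        if state.fitness[i_best] < state.best_fitness:
            state.best_fitness = float(state.fitness[i_best])
            state.best_position = state.positions[i_best].copy()
        g, w = update_constants(t, cfg)
        state.masses = compute_masses(state.fitness, cfg.eps)
        acc = accelerations(state, g, kbest_count(t, cfg), cfg, rng)
        state = move(state, acc, w, cfg, rng)
        trace.append(state.best_fitness)

    if cfg.max_iter == 0:
        state.fitness = np.array([evaluate(m) for m in state.positions])
        i_best = int(np.argmin(state.fitness))
        state.best_fitness = float(state.fitness[i_best])
        state.best_position = state.positions[i_best].copy()
        trace.append(state.best_fitness)
    else:
        # final population may contain a new best
        final = np.array([evaluate(m) for m in state.positions])
        i_best = int(np.argmin(final))
        if final[i_best] < state.best_fitness:
            state.best_fitness = float(final[i_best])
            state.best_position = state.positions[i_best].copy()
        trace[-1] = state.best_fitness

    return state.best_position, state.best_fitness, np.asarray(trace)


class CVErrorEvaluator:
    """Inner-CV error of a fast surrogate classifier on masked features.

    Retraining the full deep belief network for every agent at every
    iteration would be disproportionate; a regularized logistic surrogate
    ranks candidate subsets at a tiny fraction of the cost.  The final
    model is always the tuned network on the winning mask.

    ``origin`` maps encoded (one-hot) columns back to original feature
    indices so a D-bit mask selects whole attribute groups.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 origin: tuple[int, ...] | None = None,
                 n_splits: int = 3, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.origin = np.asarray(origin) if origin is not None \
            else np.arange(self.X.shape[1])
        self.n_splits = n_splits
        self.seed = seed
        self.n_original = int(self.origin.max()) + 1

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask).astype(bool)
        cols = np.isin(self.origin, np.flatnonzero(mask))
        if not cols.any():
            return 1.0
        Xs = self.X[:, cols]
        skf = StratifiedKFold(n_splits=self.n_splits, shuffle=True,
                              random_state=self.seed)
        errs = []
        for tr, te in skf.split(Xs, self.y):
            clf = LogisticRegression(max_iter=500)
            clf.fit(Xs[tr], self.y[tr])
            errs.append(1.0 - clf.score(Xs[te], self.y[te]))
        return float(np.mean(errs))
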