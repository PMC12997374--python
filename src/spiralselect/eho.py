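"""Elephant herding optimization of network hyperparameters.

Candidate solutions live in clans.  Each member drifts toward its clan's
matriarch (the clan best), x' = x + a (x_best − x) r with r ~ U(0,1);
the matriarch herself moves to β times the clan centre; and the worst
member of every clan is reinitialized inside the search box to keep
exploration alive.  The objective here is the inner-CV mean squared
error of the classifier trained at the candidate hyperparameters.

The hyperparameter vector is (log10 learning rate, momentum,
log10 weight decay, first-hidden-layer width); the width evolves
continuously and is rounded at evaluation time, with the second layer
half as wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dbnn import DBNNClassifier, TrainConfig

DEFAULT_BOUNDS = (
    (-4.0, -1.0),   # log10 learning rate
    (0.5, 0.99),    # momentum
    (-6.0, -2.0),   # log10 weight decay
    (16.0, 128.0),  # first hidden layer width
)


@dataclass(frozen=True)
class EHOConfig:
    """Herd geometry and stopping rule (5 clans x 10, a=0.5, β=0.7,
    tolerance 0.001)."""

    n_clans: int = 5
    clan_size: int = 10
    scale_a: float = 0.5
    clan_influence: float = 0.7
    max_iter: int = 50
    tol: float = 0.001
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.scale_a <= 1:
            raise ValueError("scale_a must lie in (0, 1]")
        if not 0 < self.clan_influence <= 1:
            raise ValueError("clan_influence must lie in (0, 1]")
        for lo, hi in self.bounds:
            if lo >= hi:
                raise ValueError("each bound must satisfy min < max")


@dataclass(frozen=True)
class HyperVector:
    """Decoded hyperparameters for one candidate network."""

    learning_rate: float
    momentum: float
    weight_decay: float
    n_hidden: int

    @classmethod
    def from_position(cls, x: Sequence[float]) -> "HyperVector":
        return cls(
            learning_rate=float(10.0 ** x[0]),
            momentum=float(x[1]),
            weight_decay=float(10.0 ** x[2]),
            n_hidden=int(round(x[3])),
        )

    @property
    def layer_sizes(self) -> tuple[int, int]:
        return (self.n_hidden, max(1, round(self.n_hidden / 2)))


def _clip(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def clan_update(x: np.ndarray, x_best: np.ndarray, a: float,
                rng: np.random.Generator) -> np.ndarray:
    """x' = x + a (x_best − x) r, r ~ U(0,1)."""
    x = np.asarray(x, dtype=float)
    x_best = np.asarray(x_best, dtype=float)
    if x.shape != x_best.shape:
        raise ValueError("dimension mismatch")
    return x + a * (x_best - x) * rng.random()


def replace_worst(positions: np.ndarray, values: np.ndarray, bounds,
                  rng: np.random.Generator) -> np.ndarray:
    """Reinitialize the clan's argmax-objective member inside the box.

    The draw x_min + (x_max − x_min + 1) rand can overshoot the upper
    bound, so the result is clamped back into the box.
    """
    if len(positions) == 0:
        raise ValueError("clan must be non-empty")
    out = positions.copy()
    worst = int(np.argmax(values))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    out[worst] = _clip(lo + (hi - lo + 1.0) * rng.random(len(bounds)),
                       bounds)
    return out


def clan_center(positions: np.ndarray) -> np.ndarray:
    """Componentwise mean of the clan."""
    if len(positions) == 0:
        raise ValueError("clan must be non-empty")
    return np.asarray(positions, dtype=float).mean(axis=0)


def center_update(center: np.ndarray, beta: float) -> np.ndarray:
    """Matriarch move: β times the clan centre."""
    return beta * np.asarray(center, dtype=float)


@dataclass
class Herd:
    """Clans of candidate positions with their objective values."""

    positions: np.ndarray  # C x S x P
    values: np.ndarray     # C x S
    best_position: np.ndarray
    best_value: float


def run_eho(objective: Callable[[np.ndarray], float], cfg: EHOConfig,
            incumbent: np.ndarray | None = None
            ) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``objective`` over the bounded box.

    Returns (best position, best value, per-iteration best-value trace).
    The global best is kept outside the herd (elitism), so clan-centre
    and worst-replacement moves can never lose it; the trace is
    non-increasing.  Stops when an iteration improves the best value by
    less than ``cfg.tol`` or after ``cfg.max_iter`` iterations.

    ``incumbent`` optionally seeds the herd with a known configuration
    (clamped into the box), so the search never returns anything its own
    objective scores worse than the configuration it started from.
    """
    rng = np.random.default_rng(cfg.seed)
    P = len(cfg.bounds)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    pos = lo + (hi - lo) * rng.random((cfg.n_clans, cfg.clan_size, P))
    if incumbent is not None:
        pos[0, 0] = _clip(np.asarray(incumbent, dtype=float), cfg.bounds)
    val = np.array([[objective(pos[c, i]) for i in range(cfg.clan_size)]
                    for c in range(cfg.n_clans)])
    flat = int(np.argmin(val))
    best_pos = pos.reshape(-1, P)[flat].copy()
    best_val = float(val.min())
    trace = [best_val]

    for _ in range(cfg.max_iter):
        prev_best = best_val
        for c in range(cfg.n_clans):
            mat = int(np.argmin(val[c]))
            center = clan_center(pos[c])
            for i in range(cfg.clan_size):
                if i == mat:
                    cand = center_update(center, cfg.clan_influence)
                else:
                    cand = clan_update(pos[c, i], pos[c, mat],
                                       cfg.scale_a, rng)
                pos[c, i] = _clip(cand, cfg.bounds)
                val[c, i] = objective(pos[c, i])
            pos[c] = replace_worst(pos[c], val[c], cfg.bounds, rng)
            worst = int(np.argmax(val[c]))
            val[c, worst] = objective(pos[c, worst])
        flat = int(np.argmin(val))
        if val.min() < best_val:
            best_val = float(val.min())
            best_pos = pos.reshape(-1, P)[flat].copy()
        trace.append(best_val)
        if prev_best - best_val < cfg.tol:
            break
    return best_pos, best_val, np.asarray(trace)


def mse_objective(X: np.ndarray, y: np.ndarray, hyper: HyperVector,
                  n_folds: int = 3, base_cfg: TrainConfig = TrainConfig(),
                  seed: int = 0) -> float:
    """Inner-CV mean squared error of the network at ``hyper``.

    For every inner split the classifier is trained on the inner-train
    rows and its one-hot targets are compared with the softmax outputs
    on the inner-validation rows: per instance the squared error sums
    over the two output units, then averages over instances; the fold
    values average to the objective.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("objective needs both classes present")
    cfg = TrainConfig(
        learning_rate=hyper.learning_rate, momentum=hyper.momentum,
        weight_decay=hyper.weight_decay, epochs=base_cfg.epochs,
        finetune_epochs=base_cfg.finetune_epochs,
        dropout_rate=base_cfg.dropout_rate, patience=base_cfg.patience,
        batch_size=base_cfg.batch_size, seed=base_cfg.seed,
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError("degenerate fold: one class absent")
        clf = DBNNClassifier(hyper.layer_sizes, cfg).fit(X[tr], y[tr])
        probs = clf.predict_proba(X[te])
        target = np.eye(2)[y[te]]
        scores.append(float(((target - probs) ** 2).sum(axis=1).mean()))
    return float(np.mean(scores))
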