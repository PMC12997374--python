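"""Deep belief network: stacked RBMs pretrained with CD-1, then a
softmax head fine-tuned by backpropagation.

Each restricted Boltzmann machine models a Boltzmann distribution
p(v, h) ∝ exp(-E(v, h)) with energy

    E(v, h) = -a·v - b·h - v' W h

over binary units; factorized sigmoid conditionals make block Gibbs
sampling and contrastive-divergence learning cheap.  The stack is
trained greedily layer by layer on the previous layer's hidden
probabilities, then unrolled into a feed-forward sigmoid network whose
softmax head is fine-tuned on the labels with dropout, L2 weight decay,
momentum SGD and early stopping.

Clinical inputs are continuous after standardization while the energy
model assumes binary visibles; the first layer therefore min–max
rescales features to [0, 1] and treats them as Bernoulli means
(mean-field visibles), a standard practical choice for tabular data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class RBMParams:
    """Weights W (visible x hidden) and biases a (visible), b (hidden)."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by pretraining and fine-tuning.

    Defaults: learning rate 0.01, momentum 0.9, L2 weight decay 1e-4,
    50 pretraining epochs, dropout 0.3, early-stopping patience 10,
    minibatch size 16.
    """

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 50
    finetune_epochs: int = 300
    dropout_rate: float = 0.3
    patience: int = 10
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


def init_rbm(n_visible: int, n_hidden: int, rng: np.random.Generator,
             scale: float | None = None) -> RBMParams:
    """Glorot-uniform weight init (scale overrides to N(0, scale²)).

    The stack unrolls into a feed-forward sigmoid network, and
    fan-balanced init keeps both the Gibbs statistics and the later
    backprop gradients in a usable range; a tiny init leaves two
    near-constant sigmoid layers and starves fine-tuning of gradient.
    """
    if scale is not None:
        W = scale * rng.standard_normal((n_visible, n_hidden))
    else:
        s = np.sqrt(6.0 / (n_visible + n_hidden))
        W = rng.uniform(-s, s, (n_visible, n_hidden))
    return RBMParams(W=W, a=np.zeros(n_visible), b=np.zeros(n_hidden))


def energy(rbm: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """E(v, h) = -a·v - b·h - v' W h."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (rbm.n_visible,) or h.shape != (rbm.n_hidden,):
        raise ValueError("state dimensions do not match the RBM")
    return float(-rbm.a @ v - rbm.b @ h - v @ rbm.W @ h)


def hidden_given_visible(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) = sigmoid(sum_i W_ij v_i + b_j); v may be a batch."""
    arr = np.asarray(v, dtype=float)
    v2 = np.atleast_2d(arr)
    if v2.shape[1] != rbm.n_visible:
        raise ValueError("visible dimension mismatch")
    p = sigmoid(v2 @ rbm.W + rbm.b)
    return p[0] if arr.ndim == 1 else p


def visible_given_hidden(rbm: RBMParams, h: np.ndarray) -> np.ndarray:
    """p(v_i = 1 | h) = sigmoid(sum_j W_ij h_j + a_i)."""
    arr = np.asarray(h, dtype=float)
    h2 = np.atleast_2d(arr)
    if h2.shape[1] != rbm.n_hidden:
        raise ValueError("hidden dimension mismatch")
    p = sigmoid(h2 @ rbm.W.T + rbm.a)
    return p[0] if arr.ndim == 1 else p


@dataclass
class _Momentum:
    dW: np.ndarray
    da: np.ndarray
    db: np.ndarray

    @classmethod
    def zeros_like(cls, rbm: RBMParams) -> "_Momentum":
        return cls(np.zeros_like(rbm.W), np.zeros_like(rbm.a),
                   np.zeros_like(rbm.b))


def cd1_step(rbm: RBMParams, batch: np.ndarray, cfg: TrainConfig,
             rng: np.random.Generator,
             mom: _Momentum | None = None) -> tuple[RBMParams, _Momentum]:
    """One CD-1 update on a batch of visible vectors (values in [0, 1]).

    Positive phase uses the data's hidden probabilities; the negative
    phase reconstructs after a single Gibbs step with sampled hidden
    states and mean-field visibles.  Weight decay applies to W only;
    momentum buffers carry across calls.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("batch must be non-empty")
    if mom is None:
        mom = _Momentum.zeros_like(rbm)
    B = batch.shape[0]
    ph = sigmoid(batch @ rbm.W + rbm.b)
    h_sample = (rng.random(ph.shape) < ph).astype(float)
    v_recon = sigmoid(h_sample @ rbm.W.T + rbm.a)
    ph_recon = sigmoid(v_recon @ rbm.W + rbm.b)

    gW = (batch.T @ ph - v_recon.T @ ph_recon) / B
    ga = (batch - v_recon).mean(axis=0)
    gb = (ph - ph_recon).mean(axis=0)

    dW = cfg.learning_rate * (gW - cfg.weight_decay * rbm.W) \
        + cfg.momentum * mom.dW
    da = cfg.learning_rate * ga + cfg.momentum * mom.da
    db = cfg.learning_rate * gb + cfg.momentum * mom.db
    new = RBMParams(rbm.W + dW, rbm.a + da, rbm.b + db)
    return new, _Momentum(dW, da, db)


def reconstruction_error(rbm: RBMParams, data: np.ndarray) -> float:
    ph = sigmoid(data @ rbm.W + rbm.b)
    v_recon = sigmoid(ph @ rbm.W.T + rbm.a)
    return float(((data - v_recon) ** 2).mean())


def train_rbm(data: np.ndarray, n_hidden: int, cfg: TrainConfig,
              rng: np.random.Generator) -> tuple[RBMParams, list[float]]:
    """Minibatch CD-1 for ``cfg.epochs`` epochs; returns loss history."""
    data = np.asarray(data, dtype=float)
    rbm = init_rbm(data.shape[1], n_hidden, rng)
    mom = _Momentum.zeros_like(rbm)
    history = []
    n = data.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            rbm, mom = cd1_step(rbm, batch, cfg, rng, mom)
        history.append(reconstruction_error(rbm, data))
    return rbm, history


def pretrain_stack(data: np.ndarray, layer_sizes: tuple[int, ...],
                   cfg: TrainConfig) -> list[RBMParams]:
    """Greedy layer-wise pretraining; layer ℓ trains on the hidden
    probabilities of layer ℓ−1."""
    rng = np.random.default_rng(cfg.seed)
    stack: list[RBMParams] = []
    inputs = np.asarray(data, dtype=float)
    for size in layer_sizes:
        rbm, _ = train_rbm(inputs, size, cfg, rng)
        stack.append(rbm)
        inputs = sigmoid(inputs @ rbm.W + rbm.b)
    return stack


@dataclass
class DBNNModel:
    """Unrolled network: hidden sigmoid layers plus a 2-unit softmax head.

    ``weights``/``biases`` include the softmax layer as the last entry.
    ``scale_min``/``scale_range`` hold the min–max rescaling fitted on
    the training inputs.
    """

    rbm_stack: list[RBMParams]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scale_min: np.ndarray | None = None
    scale_range: np.ndarray | None = None
    train_history: dict = field(default_factory=dict)
    fitted: bool = False

    @classmethod
    def from_stack(cls, stack: list[RBMParams], n_classes: int = 2,
                   rng: np.random.Generator | None = None) -> "DBNNModel":
        rng = rng or np.random.default_rng(0)
        weights = [r.W.copy() for r in stack]
        biases = [r.b.copy() for r in stack]
        weights.append(0.01 * rng.standard_normal((stack[-1].n_hidden,
                                                   n_classes)))
        biases.append(np.zeros(n_classes))
        return cls(rbm_stack=[r.copy() for r in stack],
                   weights=weights, biases=biases)

    def rescale(self, X: np.ndarray) -> np.ndarray:
        if self.scale_min is None:
            return X
        return np.clip((X - self.scale_min) / self.scale_range, 0.0, 1.0)


def _forward(weights, biases, X, dropout_masks=None):
    """Returns (pre-dropout activations, post-dropout activations, probs).

    The input row block counts as layer 0 in both lists.
    """
    pre = [X]
    post = [X]
    for i in range(len(weights) - 1):
        h = sigmoid(post[-1] @ weights[i] + biases[i])
        pre.append(h)
        post.append(h * dropout_masks[i] if dropout_masks is not None else h)
    probs = softmax(post[-1] @ weights[-1] + biases[-1])
    return pre, post, probs


def _loss_and_grads(weights, biases, X, Y, lam, dropout_masks=None):
    """Cross-entropy + (lam/2)||W||^2 loss with analytic gradients."""
    n = X.shape[0]
    pre, post, probs = _forward(weights, biases, X, dropout_masks)
    ce = -np.log(np.clip((probs * Y).sum(axis=1), 1e-12, None)).mean()
    loss = ce + 0.5 * lam * sum(float((W ** 2).sum()) for W in weights)

    gw = [None] * len(weights)
    gb = [None] * len(weights)
    delta = (probs - Y) / n  # d loss / d logits
    gw[-1] = post[-1].T @ delta + lam * weights[-1]
    gb[-1] = delta.sum(axis=0)
    for i in range(len(weights) - 2, -1, -1):
        delta = delta @ weights[i + 1].T  # w.r.t. post-dropout activation
        if dropout_masks is not None:
            delta = delta * dropout_masks[i]
        delta = delta * pre[i + 1] * (1 - pre[i + 1])  # w.r.t. preactivation
        gw[i] = post[i].T @ delta + lam * weights[i]
        gb[i] = delta.sum(axis=0)
    return loss, gw, gb


def finetune(model: DBNNModel, X_train: np.ndarray, y_train: np.ndarray,
             X_valid: np.ndarray, y_valid: np.ndarray,
             cfg: TrainConfig) -> DBNNModel:
    """Supervised fine-tuning with dropout, L2, momentum SGD and early
    stopping; returns the best-validation snapshot."""
    if len(X_valid) == 0:
        raise ValueError("validation split must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    Xt = np.asarray(X_train, dtype=float)
    Xv = np.asarray(X_valid, dtype=float)
    Yt = np.eye(2)[np.asarray(y_train, dtype=int)]
    Yv = np.eye(2)[np.asarray(y_valid, dtype=int)]

    weights = [W.copy() for W in model.weights]
    biases = [b.copy() for b in model.biases]
    vel_w = [np.zeros_like(W) for W in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    keep = 1.0 - cfg.dropout_rate

    def valid_loss(ws, bs):
        _, _, probs = _forward(ws, bs, Xv)
        return float(-np.log(np.clip((probs * Yv).sum(axis=1),
                                     1e-12, None)).mean())

    best_loss = valid_loss(weights, biases)
    init_loss = best_loss
    best = ([W.copy() for W in weights], [b.copy() for b in biases])
    history = {"train_loss": [], "valid_loss": [],
               "init_valid_loss": init_loss}
    since_best = 0
    n = Xt.shape[0]
    for _ in range(cfg.finetune_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            masks = None
            if cfg.dropout_rate > 0:
                masks = [
                    (rng.random((len(idx), W.shape[1])) < keep) / keep
                    for W in weights[:-1]
                ]
            _, gw, gb = _loss_and_grads(weights, biases, Xt[idx], Yt[idx],
                                        cfg.weight_decay, masks)
            for i in range(len(weights)):
                vel_w[i] = cfg.momentum * vel_w[i] \
                    - cfg.learning_rate * gw[i]
                vel_b[i] = cfg.momentum * vel_b[i] \
                    - cfg.learning_rate * gb[i]
                weights[i] += vel_w[i]
                biases[i] += vel_b[i]
        tl, _, _ = _loss_and_grads(weights, biases, Xt, Yt,
                                   cfg.weight_decay)
        vl = valid_loss(weights, biases)
        history["train_loss"].append(tl)
        history["valid_loss"].append(vl)
        if vl < best_loss - 1e-12:
            best_loss = vl
            best = ([W.copy() for W in weights],
                    [b.copy() for b in biases])
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    out = DBNNModel(
        rbm_stack=[r.copy() for r in model.rbm_stack],
        weights=best[0], biases=best[1],
        scale_min=model.scale_min, scale_range=model.scale_range,
        train_history={**model.train_history, **history,
                       "best_valid_loss": best_loss},
        fitted=True,
    )
    return out


def predict_proba(model: DBNNModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities; deterministic (dropout off at inference)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features; model expects "
            f"{model.weights[0].shape[0]}")
    _, _, probs = _forward(model.weights, model.biases, model.rescale(X))
    return probs


class DBNNClassifier:
    """Convenience wrapper: min–max scaling, greedy pretraining,
    supervised fine-tuning, probability prediction."""

    def __init__(self, layer_sizes: tuple[int, ...] = (64, 32),
                 cfg: TrainConfig = TrainConfig()):
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.cfg = cfg
        self.model: DBNNModel | None = None

    def fit(self, X, y, X_valid=None, y_valid=None,
            valid_fraction: float = 0.2) -> "DBNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X_valid is None:
            rng = np.random.default_rng(self.cfg.seed + 2)
            order = rng.permutation(len(X))
            n_val = max(1, int(round(valid_fraction * len(X))))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X, X_valid = X[tr_idx], X[val_idx]
            y, y_valid = y[tr_idx], y[val_idx]
        mins = X.min(axis=0)
        rng_ = X.max(axis=0) - mins
        rng_[rng_ == 0] = 1.0
        X01 = np.clip((X - mins) / rng_, 0, 1)
        Xv01 = np.clip((np.asarray(X_valid, dtype=float) - mins) / rng_, 0, 1)

        stack = pretrain_stack(X01, self.layer_sizes, self.cfg)
        model = DBNNModel.from_stack(
            stack, rng=np.random.default_rng(self.cfg.seed + 3))
        model.scale_min = mins
        model.scale_range = rng_
        # momentum SGD can diverge at aggressive rates or stall on a
        # plateau at timid ones; in both cases validation never improves
        # and the best snapshot is the useless initial state.  Retry at
        # rescaled rates and keep the best-validated attempt.
        base = self.cfg.learning_rate
        best_fit = None
        for lr in (base, base / 4.0, base * 4.0):
            cfg = dataclasses.replace(self.cfg, learning_rate=lr)
            fitted = finetune(model, X01, y, Xv01, np.asarray(y_valid), cfg)
            h = fitted.train_history
            if best_fit is None or h["best_valid_loss"] < \
                    best_fit.train_history["best_valid_loss"]:
                best_fit = fitted
            if h["best_valid_loss"] < 0.97 * h["init_valid_loss"]:
                break
        self.model = best_fit
        # scaling already applied inside fit; store for raw inputs
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        return predict_proba(self.model, np.asarray(X, dtype=float))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)
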