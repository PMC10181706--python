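"""Feed-forward MLP risk classifier trained with backpropagation.

The network maps a panel of additively coded SNPs to a two-unit softmax
head (case vs control) through fully connected hidden layers with
dropout after each.  Training minimizes the cross-entropy

    Loss = -(1/N) sum_i [ t_i log p_i + (1 - t_i) log(1 - p_i) ]

by minibatch gradient descent under one of four optimizers (sgd,
rmsprop, adam, nadam).  The default architecture is five hidden layers
of 512 tanh units with dropout probability 0.6, 200 epochs at learning
rate 1e-3 — the configuration that performs best on real chip-scale
case-control panels; a reduced profile (fewer/narrower layers) is the
sensible choice at simulation scale.

Everything is plain numpy and fully seeded, so training is reproducible
bit-for-bit in single-threaded mode.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "OPTIMIZERS",
    "TABLE_DOMAINS",
    "MLPConfig",
    "TrainedModel",
    "build_model",
    "softmax",
    "cross_entropy_loss",
    "train",
    "predict_proba",
    "grid_search",
    "default_search_space",
]

ACTIVATIONS = ("relu", "sigmoid", "tanh")
OPTIMIZERS = ("rmsprop", "nadam", "adam", "sgd")

# the published hyperparameter grid for this architecture family
TABLE_DOMAINS: dict[str, tuple] = {
    "activation": ACTIVATIONS,
    "optimizer": OPTIMIZERS,
    "epochs": (50, 100, 200, 300),
    "learning_rate": (1e-3, 1e-4, 1e-5),
    "hidden_units": (64, 128, 256, 512),
    "dropout_rate": (0.2, 0.4, 0.6),
    "batch_size": (16, 32, 64, 100),
}


@dataclass(frozen=True)
class MLPConfig:
    """One hyperparameter point.

    ``dropout_rate`` is the DROP probability (0.6 removes 60% of units
    per step).  With ``strict_domains`` (the default) every gridded field
    must come from :data:`TABLE_DOMAINS`; pass ``strict_domains=False``
    for off-grid values such as a reduced epoch budget.
    """

    n_hidden_layers: int = 5
    hidden_units: int = 512
    activation: str = "tanh"
    optimizer: str = "adam"
    epochs: int = 200
    learning_rate: float = 1e-3
    dropout_rate: float = 0.6
    batch_size: int = 32
    seed: int = 0
    strict_domains: bool = True

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1 or self.hidden_units < 1:
            raise ValueError("need at least one hidden layer and one unit")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation {self.activation!r} not in {ACTIVATIONS}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer {self.optimizer!r} not in {OPTIMIZERS}")
        if not self.strict_domains:
            return
        for name in ("epochs", "learning_rate", "hidden_units", "dropout_rate", "batch_size"):
            value = getattr(self, name)
            if value not in TABLE_DOMAINS[name]:
                raise ValueError(
                    f"{name}={value} outside the search domain {TABLE_DOMAINS[name]}; "
                    "pass strict_domains=False to override"
                )


@dataclass
class TrainedModel:
    """Layer weights/biases, the config they were trained under, and the
    per-epoch training-loss trace."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MLPConfig
    loss_trace: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    def save(self, path: str | Path, panel: list[str] | None = None) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            **{f"W{i}": w for i, w in enumerate(self.weights)},
            **{f"b{i}": b for i, b in enumerate(self.biases)},
        )
        meta = {
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "n_hidden_layers", "hidden_units", "activation", "optimizer",
                    "epochs", "learning_rate", "dropout_rate", "batch_size", "seed",
                    "strict_domains",
                )
            },
            "n_layers": len(self.weights),
            "loss_trace": self.loss_trace,
            "panel": panel,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> tuple["TrainedModel", list[str] | None]:
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        n = meta["n_layers"]
        model = cls(
            weights=[arrays[f"W{i}"] for i in range(n)],
            biases=[arrays[f"b{i}"] for i in range(n)],
            config=MLPConfig(**meta["config"]),
            loss_trace=meta["loss_trace"],
        )
        return model, meta.get("panel")


# ---------------------------------------------------------------------------
# building blocks


def softmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise normalized exponentials, max-subtracted for stability."""
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("softmax received NaN scores")
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Mean binary cross-entropy (natural log) of class-1 probabilities,
    clipped at 1e-12 so certain-but-wrong predictions stay finite."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    return 1.0 / (1.0 + np.exp(-z))  # sigmoid


def _activate_grad(a: np.ndarray, kind: str) -> np.ndarray:
    """Derivative expressed through the activation output a."""
    if kind == "relu":
        return (a > 0.0).astype(a.dtype)
    if kind == "tanh":
        return 1.0 - a**2
    return a * (1.0 - a)


def build_model(input_dim: int, config: MLPConfig) -> TrainedModel:
    """Untrained network: ``input_dim`` -> hidden layers -> 2-unit softmax.

    Weights use scaled-Gaussian (He for relu, Glorot otherwise)
    initialization from the config seed; biases start at zero.
    """
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    dims = [input_dim] + [config.hidden_units] * config.n_hidden_layers + [2]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        if config.activation == "relu":
            scale = np.sqrt(2.0 / fan_in)
        else:
            scale = np.sqrt(2.0 / (fan_in + fan_out))
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return TrainedModel(weights, biases, config)


def _forward(
    model: TrainedModel,
    x: np.ndarray,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Forward pass; dropout (inverted scaling) only when rng is given."""
    cfg = model.config
    activations = [x]
    masks: list[np.ndarray] = []
    h = x
    n_hidden = len(model.weights) - 1
    for layer in range(n_hidden):
        z = h @ model.weights[layer] + model.biases[layer]
        h = _activate(z, cfg.activation)
        if rng is not None and cfg.dropout_rate > 0.0:
            keep = 1.0 - cfg.dropout_rate
            mask = (rng.random(h.shape) < keep) / keep
            h = h * mask
            masks.append(mask)
        else:
            masks.append(np.ones_like(h))
        activations.append(h)
    logits = h @ model.weights[-1] + model.biases[-1]
    probs = softmax(logits)
    return probs, activations, masks


class _Optimizer:
    """Per-parameter state for sgd / rmsprop / adam / nadam updates."""

    def __init__(self, kind: str, lr: float, shapes: list[tuple]):
        self.kind = kind
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.rho = 0.9  # rmsprop decay

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.kind == "sgd":
                p -= self.lr * g
            elif self.kind == "rmsprop":
                self.v[i] = self.rho * self.v[i] + (1 - self.rho) * g**2
                p -= self.lr * g / (np.sqrt(self.v[i]) + self.eps)
            else:  # adam / nadam
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
                m_hat = self.m[i] / (1 - self.beta1**self.t)
                v_hat = self.v[i] / (1 - self.beta2**self.t)
                if self.kind == "nadam":
                    m_hat = self.beta1 * m_hat + (1 - self.beta1) * g / (
                        1 - self.beta1**self.t
                    )
                p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    model: TrainedModel, features: np.ndarray, labels: np.ndarray
) -> TrainedModel:
    """Minibatch backpropagation for ``config.epochs`` epochs, in place.

    No early stopping or checkpointing: the epoch budget is fixed.  The
    per-epoch mean minibatch loss is appended to ``loss_trace``.  A NaN
    loss aborts with the offending epoch.
    """
    cfg = model.config
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if x.shape[1] != model.input_dim:
        raise ValueError(f"feature width {x.shape[1]} != model input {model.input_dim}")
    n = x.shape[0]
    rng = np.random.default_rng(cfg.seed + 1)
    params = model.weights + model.biases
    opt = _Optimizer(cfg.optimizer, cfg.learning_rate, [p.shape for p in params])
    n_layers = len(model.weights)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            probs, acts, masks = _forward(model, xb, rng=rng)
            losses.append(cross_entropy_loss(yb, probs[:, 1]))

            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            delta = (probs - onehot) / len(yb)
            w_grads: list[np.ndarray] = [None] * n_layers
            b_grads: list[np.ndarray] = [None] * n_layers
            for layer in range(n_layers - 1, -1, -1):
                w_grads[layer] = acts[layer].T @ delta
                b_grads[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = delta @ model.weights[layer].T
                    delta *= masks[layer - 1]
                    delta *= _activate_grad(acts[layer], cfg.activation)
            opt.step(params, w_grads + b_grads)
        epoch_loss = float(np.mean(losses))
        if np.isnan(epoch_loss):
            raise FloatingPointError(f"training diverged (NaN loss) at epoch {epoch}")
        model.loss_trace.append(epoch_loss)
    return model


def predict_proba(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Per-sample case probability (softmax class-1 component, dropout off)."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature width {x.shape[1] if x.ndim == 2 else '?'} != model input "
            f"{model.input_dim}"
        )
    probs, _, _ = _forward(model, x, rng=None)
    return probs[:, 1]


# ---------------------------------------------------------------------------
# grid search


def default_search_space() -> dict[str, tuple]:
    """The full published grid (6,912 points; use a reduced subset for
    desk-scale runs)."""
    return dict(TABLE_DOMAINS)


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    search_space: dict[str, tuple] | None = None,
    cv_folds: int = 3,
    seed: int = 0,
    base_config: MLPConfig | None = None,
) -> tuple[MLPConfig, list[dict]]:
    """Exhaustive grid search scored by mean stratified-CV accuracy.

    Every Cartesian point of ``search_space`` (fields of
    :class:`MLPConfig`) is trained on each of ``cv_folds`` stratified
    folds and scored by mean validation accuracy; the argmax is
    returned, ties resolved by enumeration order.  Fields absent from
    the space are taken from ``base_config``.
    """
    from sklearn.model_selection import StratifiedKFold

    if search_space is None:
        search_space = default_search_space()
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("search space must be non-empty")
    base = base_config or MLPConfig(strict_domains=False)
    names = list(search_space)
    points = list(itertools.product(*(search_space[n] for n in names)))

    splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(features, labels))
    records: list[dict] = []
    best: tuple[float, int] | None = None
    for idx, values in enumerate(points):
        cfg = replace(base, **dict(zip(names, values)), seed=seed, strict_domains=False)
        accs = []
        for train_idx, val_idx in folds:
            model = build_model(features.shape[1], cfg)
            train(model, features[train_idx], labels[train_idx])
            pred = predict_proba(model, features[val_idx]) >= 0.5
            accs.append(float(np.mean(pred == labels[val_idx])))
        score = float(np.mean(accs))
        records.append({"config": cfg, "cv_accuracy": score})
        if best is None or score > best[0]:
            best = (score, idx)
    return records[best[1]]["config"], records
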