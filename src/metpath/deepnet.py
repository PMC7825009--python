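"""Feed-forward neural network for binary diagnosis classification.

A small numpy implementation shaped after the configuration surface of
grid-searchable deep learning in metabolomics pipelines: rectifier or
tanh activations, a preset menu of hidden-layer layouts, input dropout
on a 0.1 lattice, L1/L2 weight penalties, mini-batch SGD with a
classical momentum term and an ADADELTA-style per-parameter adaptive
learning rate governed by a decay factor rho, an epoch cap, and an
early-stopping rule that ends training when the misclassification rate
fails to improve by a fixed tolerance over a window of scoring rounds
(one scoring round per epoch).

`RandomDiscrete` hyperparameter search samples configurations
uniformly without replacement from the full discrete grid and keeps
the one with the best cross-validated F1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DeepNetConfig",
    "DeepNetClassifier",
    "HIDDEN_LAYER_PRESETS",
    "hyperparameter_grid",
    "grid_search_deepnet",
]

# preset hidden-layer layouts: one layer of 100 or 200; two layers of
# 10, 20 or 50 each; three layers of 30; four layers of 25
HIDDEN_LAYER_PRESETS: tuple[tuple[int, ...], ...] = (
    (100,),
    (200,),
    (10, 10),
    (20, 20),
    (50, 50),
    (30, 30, 30),
    (25, 25, 25, 25),
)

DROPOUT_GRID = tuple(round(0.1 * i, 1) for i in range(10))  # 0.0 .. 0.9
MOMENTUM_START_GRID = (0.0, 0.5)
RHO_GRID = (0.5, 0.99)


@dataclass(frozen=True)
class DeepNetConfig:
    """Hyperparameters of the feed-forward classifier.

    ``quantile_alpha`` and ``huber_alpha`` pertain to regression
    losses; binary classification uses cross-entropy, and the two
    fields are carried as inert configuration for interface fidelity.
    """

    activation: str = "rectifier"            # rectifier | tanh
    hidden_layers: tuple[int, ...] = (25, 25, 25, 25)
    input_dropout: float = 0.0               # in [0, 0.9]
    l1: float = 0.0
    l2: float = 0.0
    epochs: float = 100.0                    # cap; fractional values allowed
    momentum_start: float = 0.0
    rho: float = 0.99                        # adaptive-rate decay factor
    batch_size: int = 32
    stopping_rounds: int = 5
    stopping_tolerance: float = 0.01
    quantile_alpha: float = 1.0              # inert for classification
    huber_alpha: float = 0.9                 # inert for classification
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation not in {"rectifier", "tanh"}:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.input_dropout <= 0.9:
            raise ValueError("input_dropout must lie in [0, 0.9]")
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be >= 1")

    def on_grid(self) -> bool:
        """Whether this config lies on the discrete search lattice."""
        return (
            tuple(self.hidden_layers) in HIDDEN_LAYER_PRESETS
            and round(self.input_dropout, 1) in DROPOUT_GRID
            and abs(self.input_dropout - round(self.input_dropout, 1)) < 1e-12
            and self.momentum_start in MOMENTUM_START_GRID
            and self.rho in RHO_GRID
        )


def _act(name: str):
    if name == "tanh":
        return np.tanh, lambda pre, h: 1.0 - h * h
    return (lambda z: np.maximum(z, 0.0)), (lambda pre, h: (pre > 0).astype(float))


class DeepNetClassifier:
    """Binary feed-forward classifier trained with SGD.

    The Model/Results split is collapsed here into the scikit-learn
    fit/predict idiom so the classifier can sit in the shared
    evaluation harness next to the six classical algorithms.
    """

    def __init__(self, config: DeepNetConfig | None = None, **kwargs):
        if config is None:
            config = DeepNetConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        self.config = config
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.n_epochs_run_: int = 0
        self.score_history_: list[float] = []

    # -- internals ---------------------------------------------------------

    def _init_params(self, n_in: int, rng: np.random.Generator):
        sizes = [n_in, *self.config.hidden_layers, 1]
        self.weights_ = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases_ = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _forward(self, X: np.ndarray):
        G, _ = _act(self.config.activation)
        pres, acts = [], [X]
        a = X
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            pre = a @ W + b
            pres.append(pre)
            a = G(pre) if i < len(self.weights_) - 1 else pre
            acts.append(a)
        logits = acts[-1][:, 0]
        return pres, acts, logits

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        _, _, logits = self._forward(X)
        return logits

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    # -- training ----------------------------------------------------------

    def fit(self, X, y, validation: tuple[np.ndarray, np.ndarray] | None = None):
        """Train on binary labels; stops at the epoch cap or when the
        misclassification rate stops improving by the stopping
        tolerance within the stopping window."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("deep net supports binary labels only")
        self.classes_ = classes
        yb = (y == classes[1]).astype(float)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n, p = X.shape
        self._init_params(p, rng)
        G, Gp = _act(cfg.activation)

        # ADADELTA-style accumulators plus a momentum velocity per tensor
        eps = 1e-6
        Eg2 = [np.zeros_like(W) for W in self.weights_] + [np.zeros_like(b) for b in self.biases_]
        Ex2 = [np.zeros_like(a) for a in Eg2]
        vel = [np.zeros_like(a) for a in Eg2]

        n_batches = max(1, int(np.ceil(n / cfg.batch_size)))
        max_epochs = int(np.ceil(cfg.epochs))
        Xs, ys = (X, yb) if validation is None else (np.asarray(validation[0], float),
                                                    (np.asarray(validation[1]) == classes[1]).astype(float))
        self.score_history_ = []
        best_err = np.inf
        best_round = 0
        steps_total = int(np.ceil(cfg.epochs * n_batches))
        step = 0
        for epoch in range(max_epochs):
            perm = rng.permutation(n)
            for bstart in range(0, n, cfg.batch_size):
                if step >= steps_total:
                    break
                idx = perm[bstart : bstart + cfg.batch_size]
                xb = X[idx]
                if cfg.input_dropout > 0:
                    mask = rng.random(xb.shape) >= cfg.input_dropout
                    xb = xb * mask / (1.0 - cfg.input_dropout)
                pres, acts, logits = self._forward(xb)
                prob = 1.0 / (1.0 + np.exp(-logits))
                delta = ((prob - yb[idx]) / len(idx))[:, None]
                grads_W, grads_b = [], []
                for i in range(len(self.weights_) - 1, -1, -1):
                    gW = acts[i].T @ delta
                    gW += cfg.l2 * self.weights_[i] + cfg.l1 * np.sign(self.weights_[i])
                    gb = delta.sum(axis=0)
                    grads_W.insert(0, gW)
                    grads_b.insert(0, gb)
                    if i > 0:
                        delta = (delta @ self.weights_[i].T) * Gp(pres[i - 1], acts[i])
                grads = grads_W + grads_b
                params = self.weights_ + self.biases_
                for j, (prm, g) in enumerate(zip(params, grads)):
                    Eg2[j] = cfg.rho * Eg2[j] + (1 - cfg.rho) * g * g
                    upd = -np.sqrt(Ex2[j] + eps) / np.sqrt(Eg2[j] + eps) * g
                    Ex2[j] = cfg.rho * Ex2[j] + (1 - cfg.rho) * upd * upd
                    vel[j] = cfg.momentum_start * vel[j] + upd
                    prm += vel[j]
                step += 1
            self.n_epochs_run_ = epoch + 1
            # scoring round: misclassification on the validation (or training) set
            err = float(np.mean((self.decision_function(Xs) > 0).astype(float) != ys))
            self.score_history_.append(err)
            rnd = len(self.score_history_)
            if err < best_err - cfg.stopping_tolerance:
                best_err = err
                best_round = rnd
            if rnd - best_round >= cfg.stopping_rounds:
                break
            if step >= steps_total:
                break
        return self

    # sklearn-compatible surface for the shared harness
    def get_params(self, deep: bool = True):
        return {"config": self.config}

    def set_params(self, **kwargs):
        if "config" in kwargs:
            self.config = kwargs.pop("config")
        if kwargs:
            self.config = replace(self.config, **kwargs)
        return self


def hyperparameter_grid() -> list[DeepNetConfig]:
    """The full discrete search lattice (activation x layout x dropout
    x momentum start x rho); epoch cap 500."""
    grid = []
    for act, layers, drop, mom, rho in itertools.product(
        ("rectifier", "tanh"), HIDDEN_LAYER_PRESETS, DROPOUT_GRID,
        MOMENTUM_START_GRID, RHO_GRID,
    ):
        grid.append(
            DeepNetConfig(
                activation=act,
                hidden_layers=layers,
                input_dropout=drop,
                momentum_start=mom,
                rho=rho,
                epochs=500.0,
            )
        )
    return grid


def _cv_f1(config: DeepNetConfig, X, y, cv_folds: int, seed: int, epochs: float) -> float:
    from sklearn.model_selection import StratifiedKFold

    from .classify import compute_metrics, confusion_counts

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    for tr, te in skf.split(X, y):
        clf = DeepNetClassifier(replace(config, epochs=epochs, seed=seed))
        clf.fit(X[tr], y[tr])
        pred = clf.classes_[clf.predict(X[te])]
        c = confusion_counts(y[te], pred, positive=clf.classes_[1])
        tp += c.TP; fp += c.FP; tn += c.TN; fn += c.FN
    from .classify import ConfusionCounts

    return compute_metrics(ConfusionCounts(tp, fp, tn, fn)).f1


def grid_search_deepnet(
    X,
    y,
    budget: int = 100,
    seed: int = 0,
    cv_folds: int = 3,
    epochs: float | None = None,
) -> tuple[DeepNetConfig, "DeepNetClassifier", list[tuple[DeepNetConfig, float]]]:
    """RandomDiscrete search over the hyperparameter lattice.

    Samples up to ``budget`` configurations uniformly without
    replacement (a budget at or above the grid size evaluates the
    whole grid), scores each by ``cv_folds``-fold CV F1, refits the
    winner on all data, and returns (best config, fitted model, all
    evaluated (config, F1) pairs).  ``epochs`` can lower the per-model
    epoch cap for desk-scale runs.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    grid = hyperparameter_grid()
    rng = np.random.default_rng(seed)
    if budget >= len(grid):
        chosen = list(range(len(grid)))
    else:
        chosen = list(rng.choice(len(grid), size=budget, replace=False))
    results = []
    for i in chosen:
        cfg = grid[i]
        eff_epochs = epochs if epochs is not None else cfg.epochs
        f1 = _cv_f1(cfg, X, y, cv_folds, seed, eff_epochs)
        results.append((cfg, f1))
    best_cfg, _ = max(results, key=lambda t: t[1])
    eff_epochs = epochs if epochs is not None else best_cfg.epochs
    best_model = DeepNetClassifier(replace(best_cfg, epochs=eff_epochs, seed=seed)).fit(X, y)
    return best_cfg, best_model, results
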