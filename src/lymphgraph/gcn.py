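"""Two-layer graph convolutional network for transductive node classification.

The propagation rule per layer is

    H^(l+1) = ReLU( P H^(l) W^(l) ),   P = D̃^(-1/2) (A + I) D̃^(-1/2),

with H^(0) = X (the selected patient features). The second layer's output
passes through dropout and a dense softmax head,

    Z = softmax( H^(2) W_fc ),

giving per-node class probabilities. Training is Adam on the cross-entropy
of the training-visible nodes, mini-batched over the *loss* nodes: every
step runs the full-graph propagation (the graph is indivisible) but the
cross-entropy is taken over a 32-node batch of training nodes, so one epoch
makes ``ceil(n_visible / batch_size)`` gradient steps. A stratified
internal subset of training nodes (default 15%) is masked out of the loss
and monitored for early stopping with patience; the parameters from the
best-monitored epoch are returned. ``batch_size=0`` requests classical
full-batch steps (one per epoch).

Everything — initialization, dropout masks, the early-stop split — is
seeded, so training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from ._utils import as_binary_labels
from .graph import NodeTable, PatientGraph, assemble_graph


@dataclass(frozen=True)
class GCNConfig:
    hidden1: int = 64
    hidden2: int = 32
    dropout_rate: float = 0.5
    learning_rate: float = 1e-4
    max_epochs: int = 500
    patience: int = 50
    early_stop_fraction: float = 0.15
    seed: int = 0
    n_classes: int = 2
    batch_size: int = 32  # loss-node mini-batch size; 0 = full batch

    def __post_init__(self) -> None:
        if self.hidden1 < 1 or self.hidden2 < 1:
            raise ValueError("hidden sizes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 0 or self.patience < 1:
            raise ValueError("max_epochs >= 0 and patience >= 1 required")
        if self.batch_size < 0:
            raise ValueError("batch_size must be >= 0 (0 = full batch)")
        if not 0.0 <= self.early_stop_fraction < 0.5:
            raise ValueError("early_stop_fraction must lie in [0, 0.5)")


@dataclass
class GCNParams:
    W0: np.ndarray
    W1: np.ndarray
    W_fc: np.ndarray

    def __post_init__(self) -> None:
        for name in ("W0", "W1", "W_fc"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    def copy(self) -> "GCNParams":
        return GCNParams(self.W0.copy(), self.W1.copy(), self.W_fc.copy())

    def to_json(self, path: str | Path, config: GCNConfig | None = None) -> Path:
        path = Path(path)
        payload = {
            "W0": self.W0.tolist(),
            "W1": self.W1.tolist(),
            "W_fc": self.W_fc.tolist(),
            "config": None if config is None else vars(config) | {},
        }
        if config is not None:
            payload["config"] = {k: getattr(config, k) for k in config.__dataclass_fields__}
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GCNParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            W0=np.asarray(payload["W0"], dtype=float),
            W1=np.asarray(payload["W1"], dtype=float),
            W_fc=np.asarray(payload["W_fc"], dtype=float),
        )


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    mask_loss: list[float] = field(default_factory=list)
    mask_acc: list[float] = field(default_factory=list)
    epoch_stopped: int = 0
    best_epoch: int = 0

    def to_csv(self, path: str | Path) -> Path:
        import csv

        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_acc", "mask_loss", "mask_acc"])
            for e in range(len(self.train_loss)):
                w.writerow(
                    [e, self.train_loss[e], self.train_acc[e], self.mask_loss[e], self.mask_acc[e]]
                )
        return path


def one_hot(labels, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes}), got range "
                         f"[{labels.min()}, {labels.max()}]")
    return np.eye(n_classes)[labels]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def glorot_init(config: GCNConfig, d: int, seed: int | None = None) -> GCNParams:
    """Glorot-uniform weights for input width d, seeded."""
    rng = np.random.default_rng(config.seed if seed is None else seed)

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return GCNParams(
        W0=glorot(d, config.hidden1),
        W1=glorot(config.hidden1, config.hidden2),
        W_fc=glorot(config.hidden2, config.n_classes),
    )


def forward(
    p_hat,
    X: np.ndarray,
    params: GCNParams,
    dropout_rate: float = 0.0,
    dropout_active: bool = False,
    seed: int = 0,
):
    """Evaluate the network; returns (Z, H1, H2, cache-for-backprop).

    ``p_hat`` may be dense or scipy-sparse. Dropout (inverted scaling) is
    applied to H^(2) only when ``dropout_active``.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if p_hat.shape != (n, n):
        raise ValueError(f"p_hat shape {p_hat.shape} does not match n={n}")
    if params.W0.shape[0] != d:
        raise ValueError(f"W0 expects input width {params.W0.shape[0]}, got {d}")

    A1 = p_hat @ (X @ params.W0)
    H1 = np.maximum(A1, 0.0)
    A2 = p_hat @ (H1 @ params.W1)
    H2 = np.maximum(A2, 0.0)
    if dropout_active and dropout_rate > 0.0:
        mask = (np.random.default_rng(seed).random(H2.shape) >= dropout_rate) / (1.0 - dropout_rate)
    else:
        mask = np.ones_like(H2)
    H2d = H2 * mask
    logits = H2d @ params.W_fc
    Z = _softmax(logits)
    cache = {"A1": A1, "H1": H1, "A2": A2, "H2": H2, "mask": mask, "H2d": H2d}
    return Z, H1, H2, cache


def _loss_and_grads(p_hat, X, params: GCNParams, y_onehot, visible, dropout_rate, seed):
    """Cross-entropy on ``visible`` nodes and analytic gradients."""
    Z, _, _, c = forward(p_hat, X, params, dropout_rate, dropout_active=dropout_rate > 0, seed=seed)
    m = int(visible.sum())
    eps = 1e-12
    loss = -np.sum(visible[:, None] * y_onehot * np.log(Z + eps)) / m

    dlogits = (Z - y_onehot) * visible[:, None] / m
    gW_fc = c["H2d"].T @ dlogits
    dH2 = (dlogits @ params.W_fc.T) * c["mask"]
    dA2 = dH2 * (c["A2"] > 0)
    PH1 = p_hat @ c["H1"]
    gW1 = PH1.T @ dA2
    dH1 = p_hat.T @ (dA2 @ params.W1.T)
    dA1 = dH1 * (c["A1"] > 0)
    PX = p_hat @ X
    gW0 = PX.T @ dA1
    return loss, Z, GCNParams(gW0, gW1, gW_fc)


def _adam_state(params: GCNParams):
    zeros = lambda a: np.zeros_like(a)
    return {
        "m": GCNParams(zeros(params.W0), zeros(params.W1), zeros(params.W_fc)),
        "v": GCNParams(zeros(params.W0), zeros(params.W1), zeros(params.W_fc)),
        "t": 0,
    }


def _adam_step(params: GCNParams, grads: GCNParams, state, lr, b1=0.9, b2=0.999, eps=1e-8):
    state["t"] += 1
    t = state["t"]
    for name in ("W0", "W1", "W_fc"):
        g = getattr(grads, name)
        m = getattr(state["m"], name)
        v = getattr(state["v"], name)
        m *= b1; m += (1 - b1) * g
        v *= b2; v += (1 - b2) * g * g
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        getattr(params, name)[...] -= lr * mhat / (np.sqrt(vhat) + eps)


def train(
    graph: PatientGraph,
    labels=None,
    config: GCNConfig = GCNConfig(),
) -> tuple[GCNParams, TrainHistory]:
    """Full-batch Adam training on one cohort graph.

    A stratified ``early_stop_fraction`` of nodes is removed from the loss
    and used only to monitor early stopping (patience on its cross-entropy);
    the returned parameters are those of the best-monitored epoch. With
    ``early_stop_fraction = 0`` the monitor is the training loss itself.
    """
    y = as_binary_labels(graph.y if labels is None else labels)
    n = graph.n_nodes
    if y.shape[0] != n:
        raise ValueError("label count does not match graph size")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")

    X = graph.X
    p_hat = graph.p_hat_sparse() if n > 200 else graph.p_hat
    y1h = one_hot(y, config.n_classes)

    rng = np.random.default_rng(config.seed)
    visible = np.ones(n, dtype=bool)
    monitor = visible
    if config.early_stop_fraction > 0 and n >= 10:
        idx_train, idx_mask = train_test_split(
            np.arange(n),
            test_size=config.early_stop_fraction,
            stratify=y,
            random_state=int(rng.integers(2**31 - 1)),
        )
        visible = np.zeros(n, dtype=bool)
        visible[idx_train] = True
        monitor = np.zeros(n, dtype=bool)
        monitor[idx_mask] = True

    params = glorot_init(config, X.shape[1])
    history = TrainHistory()
    if config.max_epochs == 0:
        return params, history

    state = _adam_state(params)
    best_loss = np.inf
    best_params = params.copy()
    best_epoch = 0
    since_best = 0
    eps = 1e-12

    visible_idx = np.flatnonzero(visible)
    batch = config.batch_size if config.batch_size > 0 else visible_idx.size

    for epoch in range(config.max_epochs):
        order = rng.permutation(visible_idx)
        for start in range(0, order.size, batch):
            step_visible = np.zeros(n, dtype=bool)
            step_visible[order[start : start + batch]] = True
            drop_seed = int(rng.integers(2**31 - 1))
            _, _, grads = _loss_and_grads(
                p_hat, X, params, y1h, step_visible, config.dropout_rate, drop_seed
            )
            _adam_step(params, grads, state, config.learning_rate)

        # evaluation pass without dropout
        Z_eval, _, _, _ = forward(p_hat, X, params)
        pred = np.argmax(Z_eval, axis=1)
        tr_loss = -np.mean(np.log(Z_eval[visible, y[visible]] + eps))
        mk_loss = -np.mean(np.log(Z_eval[monitor, y[monitor]] + eps))
        history.train_loss.append(float(tr_loss))
        history.train_acc.append(float(np.mean(pred[visible] == y[visible])))
        history.mask_loss.append(float(mk_loss))
        history.mask_acc.append(float(np.mean(pred[monitor] == y[monitor])))

        if mk_loss < best_loss - 1e-12:
            best_loss = mk_loss
            best_params = params.copy()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    history.epoch_stopped = len(history.train_loss)
    history.best_epoch = best_epoch
    return best_params, history


def predict(graph: PatientGraph, params: GCNParams) -> np.ndarray:
    """Positive-class probability per node (dropout inactive, deterministic)."""
    p_hat = graph.p_hat_sparse() if graph.n_nodes > 200 else graph.p_hat
    Z, _, _, _ = forward(p_hat, graph.X, params)
    return Z[:, 1]


class GCNNodeClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style wrapper: cosine graph construction + GCN training.

    ``fit(X, y)`` builds the training cohort's similarity graph at
    ``threshold`` and trains the network; ``predict_proba(X)`` builds a new
    graph over the given cohort and runs the trained weights on it — the
    transductive analogue of out-of-sample prediction, matching evaluation
    on separate per-hospital validation graphs.
    """

    def __init__(
        self,
        threshold: float = 0.6,
        hidden1: int = 64,
        hidden2: int = 32,
        dropout_rate: float = 0.5,
        learning_rate: float = 1e-4,
        max_epochs: int = 500,
        patience: int = 50,
        early_stop_fraction: float = 0.15,
        seed: int = 0,
    ):
        self.threshold = threshold
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.early_stop_fraction = early_stop_fraction
        self.seed = seed

    def _config(self) -> GCNConfig:
        return GCNConfig(
            hidden1=self.hidden1,
            hidden2=self.hidden2,
            dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
            early_stop_fraction=self.early_stop_fraction,
            seed=self.seed,
        )

    def fit(self, X, y, ids: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = as_binary_labels(y)
        ids = ids if ids is not None else [f"N{i}" for i in range(X.shape[0])]
        table = NodeTable(ids=ids, X=X, y=y)
        self.graph_ = assemble_graph(table, self.threshold)
        self.params_, self.history_ = train(self.graph_, config=self._config())
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _cohort_graph(self, X, ids=None) -> PatientGraph:
        X = np.asarray(X, dtype=float)
        ids = ids if ids is not None else [f"N{i}" for i in range(X.shape[0])]
        table = NodeTable(ids=ids, X=X, y=np.zeros(X.shape[0], dtype=int))
        return assemble_graph(table, self.threshold)

    def predict_proba(self, X, ids: list[str] | None = None) -> np.ndarray:
        p1 = predict(self._cohort_graph(X, ids), self.params_)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X, cutoff: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= cutoff).astype(int)
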