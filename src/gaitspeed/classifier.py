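"""Bidirectional LSTM walking-speed classifier, implemented in numpy.

The network is the five-layer stack used for the speed-classification
task: sequence input of size 5 (one channel per ratio feature), a biLSTM
layer with 100 hidden units per direction whose final forward and
backward states are concatenated, a fully connected layer with one
output per speed class, softmax, and cross-entropy loss.  Training uses
the adaptive moment estimation (Adam) optimizer with gradient clipping
by global L2 norm, fixed mini-batch order (no shuffling) and periodic
validation checks.

Everything — forward pass, backpropagation through time, Adam — is
implemented directly on numpy arrays in float32, which keeps runs
bit-reproducible for a given seed and fast enough for the repeated
cross-validation experiments on a single CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .signals import WalkingSpeedPattern

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "BiLSTMModel",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "accuracy_percent",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture: 5 inputs, 100 hidden units per direction, 3 classes.

    ``hidden_units`` counts units per direction (the concatenated final
    state is ``2 * hidden_units`` wide), matching the convention of the
    framework the training options were specified for.
    """

    input_size: int = 5
    hidden_units: int = 100
    n_classes: int = 3


@dataclass(frozen=True)
class TrainingConfig:
    """Training options for the cross-validation experiments.

    Defaults: Adam with initial learning rate 0.001 and squared-gradient
    decay 0.99 (first-moment decay 0.9, the framework default), gradient
    clipping by global L2 norm at threshold 0.9, at most 200 epochs,
    mini-batches of 27 patterns taken in fixed order (shuffle "never",
    the partial final batch is used), and a validation-accuracy check
    every 22 iterations.
    """

    learning_rate: float = 0.001
    first_moment_decay: float = 0.9
    squared_grad_decay: float = 0.99
    grad_threshold: float = 0.9
    max_epochs: int = 200
    mini_batch: int = 27
    validation_frequency: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.grad_threshold, self.max_epochs,
               self.mini_batch, self.validation_frequency) < 0:
            raise ValueError("training options must be non-negative")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32)


def _orthogonal_gates(rng: np.random.Generator, n: int, n_gates: int = 4) -> np.ndarray:
    """Recurrent weights: one orthogonal n x n block per gate, concatenated."""
    blocks = []
    for _ in range(n_gates):
        a = rng.standard_normal((n, n))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))  # fix the sign ambiguity for determinism
        blocks.append(q.astype(np.float32))
    return np.concatenate(blocks, axis=1)


class BiLSTMModel:
    """The parameter container plus forward/backward machinery.

    Parameters per direction ``d``: input weights ``W_d`` (I x 4H,
    Glorot-uniform), recurrent weights ``R_d`` (H x 4H, per-gate
    orthogonal), bias ``b_d`` (4H, zeros); plus the fully connected layer
    ``fc_W`` (2H x C) and ``fc_b`` (C,).  Gate order within the 4H axis
    is input, forget, cell-candidate, output.
    """

    PARAM_NAMES = ("W_f", "R_f", "b_f", "W_b", "R_b", "b_b", "fc_W", "fc_b")

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        I, H, C = config.input_size, config.hidden_units, config.n_classes
        self.params: dict[str, np.ndarray] = {}
        for d in ("f", "b"):
            self.params[f"W_{d}"] = _glorot(rng, I, 4 * H)
            self.params[f"R_{d}"] = _orthogonal_gates(rng, H)
            self.params[f"b_{d}"] = np.zeros(4 * H, dtype=np.float32)
        self.params["fc_W"] = _glorot(rng, 2 * H, C)
        self.params["fc_b"] = np.zeros(C, dtype=np.float32)

    # ---------------------------------------------------------------- forward

    def _run_direction(self, x: np.ndarray, d: str, keep_cache: bool):
        """Run one LSTM direction over x (B, T, I) in temporal order.

        For the backward direction the caller passes the time-reversed
        input; the returned final state is then the state after reading
        the whole sequence in reverse.
        """
        B, T, I = x.shape
        H = self.config.hidden_units
        W, R, b = self.params[f"W_{d}"], self.params[f"R_{d}"], self.params[f"b_{d}"]
        dt = W.dtype
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        cache = {k: np.empty((T, B, H), dtype=dt)
                 for k in ("i", "f", "g", "o", "c", "tc", "h_prev", "c_prev")} if keep_cache else None
        xWb = x.reshape(B * T, I) @ W
        xWb = xWb.reshape(B, T, 4 * H) + b
        for t in range(T):
            z = xWb[:, t, :] + h @ R
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            if keep_cache:
                cache["h_prev"][t] = h
                cache["c_prev"][t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            if keep_cache:
                cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t] = i, f, g, o
                cache["c"][t], cache["tc"][t] = c, tc
        return h, cache

    def forward(self, X: np.ndarray, keep_cache: bool = False):
        """Class probabilities for X (B, T, I); rows sum to 1."""
        X = np.ascontiguousarray(X, dtype=self.params["W_f"].dtype)
        if X.ndim != 3 or X.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected input of shape (batch, T, {self.config.input_size}), got {X.shape}"
            )
        h_f, cache_f = self._run_direction(X, "f", keep_cache)
        Xr = np.ascontiguousarray(X[:, ::-1, :])
        h_b, cache_b = self._run_direction(Xr, "b", keep_cache)
        feats = np.concatenate([h_f, h_b], axis=1)
        logits = feats @ self.params["fc_W"] + self.params["fc_b"]
        probs = _softmax(logits)
        if keep_cache:
            return probs, {"X": X, "Xr": Xr, "f": cache_f, "b": cache_b, "feats": feats}
        return probs

    # --------------------------------------------------------------- backward

    def _backprop_direction(self, x: np.ndarray, cache, dh_last: np.ndarray, d: str):
        B, T, I = x.shape
        H = self.config.hidden_units
        R = self.params[f"R_{d}"]
        dW = np.zeros_like(self.params[f"W_{d}"])
        dR = np.zeros_like(R)
        db = np.zeros_like(self.params[f"b_{d}"])
        dt = R.dtype
        dh = dh_last.astype(dt)
        dc = np.zeros((B, H), dtype=dt)
        dz_all = np.empty((T, B, 4 * H), dtype=dt)
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            tc, c_prev, h_prev = cache["tc"][t], cache["c_prev"][t], cache["h_prev"][t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            dz = dz_all[t]
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
            dz[:, 3 * H:] = do * o * (1.0 - o)
            dR += h_prev.T @ dz
            dh = dz @ R.T
            dc = dc * f
        # accumulate input-weight grads in one big matmul
        dW = x.reshape(B * T, I).T @ dz_all.transpose(1, 0, 2).reshape(B * T, 4 * H)
        db = dz_all.sum(axis=(0, 1))
        return dW, dR, db

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean cross-entropy over the batch and grads for every parameter."""
        probs, cache = self.forward(X, keep_cache=True)
        B = X.shape[0]
        eps = np.finfo(np.float32).tiny
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {}
        grads["fc_W"] = cache["feats"].T @ dlogits
        grads["fc_b"] = dlogits.sum(axis=0)
        dfeats = dlogits @ self.params["fc_W"].T
        H = self.config.hidden_units
        for d, x_d, dh in (("f", cache["X"], dfeats[:, :H]), ("b", cache["Xr"], dfeats[:, H:])):
            dW, dR, db = self._backprop_direction(x_d, cache[d], dh, d)
            grads[f"W_{d}"], grads[f"R_{d}"], grads[f"b_{d}"] = dW, dR, db
        return loss, grads


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedModel:
    """A trained classifier plus its training history.

    ``history`` holds per-iteration training losses; ``validation_checks``
    holds (iteration, validation accuracy %) pairs recorded every
    ``validation_frequency`` iterations.
    """

    model: BiLSTMModel
    train_config: TrainingConfig
    history: list[float] = field(default_factory=list)
    validation_checks: list[tuple[int, float]] = field(default_factory=list)

    @property
    def config(self) -> ModelConfig:
        return self.model.config


def build_model(config: ModelConfig | None = None, seed: int = 0) -> BiLSTMModel:
    """Fresh model with seeded Glorot/orthogonal/zero initialization."""
    return BiLSTMModel(config or ModelConfig(), seed=seed)


def clip_global_norm(grads: dict[str, np.ndarray], threshold: float) -> float:
    """Scale all gradients in place so their global L2 norm <= threshold.

    Returns the pre-clip norm.  Norms at or below the threshold leave the
    gradients untouched.
    """
    gnorm = float(
        np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
    )
    if gnorm > threshold:
        scale = np.float32(threshold / gnorm)
        for g in grads.values():
            g *= scale
    return gnorm


def _patterns_to_arrays(patterns: Sequence[WalkingSpeedPattern]):
    X = np.stack([p.signals.T for p in patterns]).astype(np.float32)  # (N, T, 5)
    y = np.array([p.label for p in patterns], dtype=np.int64)
    return X, y


def train(
    model: BiLSTMModel,
    train_patterns: Sequence[WalkingSpeedPattern],
    val_patterns: Sequence[WalkingSpeedPattern] = (),
    config: TrainingConfig | None = None,
) -> TrainedModel:
    """Mini-batch Adam training; returns the final-epoch model.

    Batches are taken in the fixed input order every epoch (no
    shuffling); the partial final batch is used.  Gradients are clipped
    so their global L2 norm never exceeds ``grad_threshold``.  No early
    stopping or checkpoint selection: the model after the last epoch is
    returned, with validation accuracy logged along the way.
    """
    cfg = config or TrainingConfig()
    if len(train_patterns) == 0:
        raise ValueError("empty training set")
    X, y = _patterns_to_arrays(train_patterns)
    Xv, yv = (None, None)
    if len(val_patterns):
        Xv, yv = _patterns_to_arrays(val_patterns)

    b1, b2, lr, eps = cfg.first_moment_decay, cfg.squared_grad_decay, cfg.learning_rate, 1e-8
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    trained = TrainedModel(model, cfg)

    n = len(X)
    batch_starts = list(range(0, n, cfg.mini_batch))
    it = 0
    for _epoch in range(cfg.max_epochs):
        for s in batch_starts:
            xb, yb = X[s:s + cfg.mini_batch], y[s:s + cfg.mini_batch]
            loss, grads = model.loss_and_grads(xb, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss} at iteration {it}"
                )
            clip_global_norm(grads, cfg.grad_threshold)
            it += 1
            bc1 = 1.0 - b1 ** it
            bc2 = 1.0 - b2 ** it
            for k, g in grads.items():
                m_state[k] = b1 * m_state[k] + (1 - b1) * g
                v_state[k] = b2 * v_state[k] + (1 - b2) * g * g
                step = lr * (m_state[k] / bc1) / (np.sqrt(v_state[k] / bc2) + eps)
                model.params[k] -= step.astype(np.float32)
            trained.history.append(loss)
            if Xv is not None and it % cfg.validation_frequency == 0:
                acc = _accuracy_arrays(model, Xv, yv)
                trained.validation_checks.append((it, acc))
    return trained


def predict(model: TrainedModel | BiLSTMModel, patterns: Sequence[WalkingSpeedPattern]):
    """Predicted labels and the probability matrix for a pattern batch.

    The label is the argmax of the softmax probabilities; exact ties
    resolve to the lowest class index.
    """
    net = model.model if isinstance(model, TrainedModel) else model
    X, _ = _patterns_to_arrays(patterns)
    probs = _forward_batched(net, X)
    return probs.argmax(axis=1), probs


def accuracy_percent(model: TrainedModel | BiLSTMModel, patterns: Sequence[WalkingSpeedPattern]) -> float:
    """Classification accuracy (%) on a labeled pattern set."""
    net = model.model if isinstance(model, TrainedModel) else model
    X, y = _patterns_to_arrays(patterns)
    return _accuracy_arrays(net, X, y)


def _forward_batched(net: BiLSTMModel, X: np.ndarray, batch: int = 64) -> np.ndarray:
    return np.concatenate([net.forward(X[s:s + batch]) for s in range(0, len(X), batch)])


def _accuracy_arrays(net: BiLSTMModel, X: np.ndarray, y: np.ndarray) -> float:
    pred = _forward_batched(net, X).argmax(axis=1)
    return float(100.0 * np.mean(pred == y))


# ------------------------------------------------------------- serialization

def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Save weights (+ configs) as an .npz next to a .json sidecar."""
    path = Path(path)
    np.savez(path, **trained.model.params)
    meta = {
        "model_config": asdict(trained.model.config),
        "train_config": asdict(trained.train_config),
        "seed": trained.model.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = BiLSTMModel(ModelConfig(**meta["model_config"]), seed=meta["seed"])
    with np.load(path.with_suffix(".npz")) as data:
        for k in model.PARAM_NAMES:
            model.params[k] = data[k]
    return TrainedModel(model, TrainingConfig(**meta["train_config"]))
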