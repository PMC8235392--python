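"""Two-layer LSTM classifier over impedance spectra, from scratch in numpy.

Each example is one 36-point spectrum; the recurrence runs along the
frequency axis (ascending), so the network can carry information across
the spectrum the way it would across time.  Architecture: LSTM layer ->
per-step batch normalization -> dropout -> LSTM layer -> dense softmax
head over the final hidden state.  Training is mini-batch Adam on
cross-entropy with an L2 (ridge) penalty on the weight matrices, with
early stopping on held-out loss.  All gradients are exact
backpropagation-through-time and are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .errors import TrainingError, ValidationError

WEIGHT_KEYS = ("lstm1.Wx", "lstm1.Wh", "lstm2.Wx", "lstm2.Wh", "dense.W")
ALL_KEYS = WEIGHT_KEYS + ("lstm1.b", "lstm2.b", "dense.b", "bn.gamma", "bn.beta")


@dataclass(frozen=True)
class LSTMConfig:
    """Hyperparameters; none were published, so these are package defaults."""

    hidden_units: int = 32
    dropout_rate: float = 0.4
    l2_penalty: float = 1e-4
    learning_rate: float = 3e-3
    batch_size: int = 16
    max_epochs: int = 300
    patience: int = 60
    seed: int = 0
    input_channel: str = "X"
    train_fraction: float = 0.8
    bn_momentum: float = 0.9
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValidationError("hidden_units must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if min(self.l2_penalty, self.learning_rate) < 0:
            raise ValidationError("rates/penalties must be non-negative")
        if self.input_channel not in ("R", "X"):
            raise ValidationError("input_channel must be 'R' or 'X'")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def init_parameters(config: LSTMConfig, seq_len: int, rng: np.random.Generator) -> dict:
    """Glorot-uniform weights, zero biases except forget-gate bias = 1."""
    H = config.hidden_units

    def glorot(shape):
        limit = math.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape)

    params = {
        "lstm1.Wx": glorot((1, 4 * H)),
        "lstm1.Wh": glorot((H, 4 * H)),
        "lstm1.b": np.zeros(4 * H),
        "lstm2.Wx": glorot((H, 4 * H)),
        "lstm2.Wh": glorot((H, 4 * H)),
        "lstm2.b": np.zeros(4 * H),
        "bn.gamma": np.ones(H),
        "bn.beta": np.zeros(H),
        "dense.W": glorot((H, 2)),
        "dense.b": np.zeros(2),
    }
    for key in ("lstm1.b", "lstm2.b"):
        params[key][H : 2 * H] = 1.0  # forget gate
    return params


@dataclass
class ClassifierModel:
    """Weights plus the normalization state needed to score new spectra."""

    config: LSTMConfig
    params: dict
    running_mean: np.ndarray  # (T, H) batch-norm running means
    running_var: np.ndarray  # (T, H)
    x_mean: np.ndarray  # (T,) per-frequency input standardization
    x_std: np.ndarray  # (T,)
    classes: tuple = ("fast_thaw", "slow_thaw")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) / self.x_std

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for raw (n, T) spectra, evaluation mode."""
        probs, _ = lstm_forward(self, self.standardize(X)[:, :, None], training_mode=False)
        return probs

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "classes": list(self.classes),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "running_mean": self.running_mean.tolist(),
            "running_var": self.running_var.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            config=LSTMConfig(**d["config"]),
            params={k: np.asarray(v, dtype=float) for k, v in d["params"].items()},
            running_mean=np.asarray(d["running_mean"], dtype=float),
            running_var=np.asarray(d["running_var"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_std=np.asarray(d["x_std"], dtype=float),
            classes=tuple(d["classes"]),
        )


# ---------------------------------------------------------------------------
# forward / backward


def _lstm_layer_forward(Wx, Wh, b, X):
    """X (B, T, D) -> hidden states (B, T, H) plus per-step caches."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    caches = []
    for t in range(T):
        a = X[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        caches.append((X[:, t], h, c, i, f, g, o, tanh_c))
        h, c = h_new, c_new
        Hs[:, t] = h
    return Hs, caches


def _lstm_layer_backward(Wx, Wh, caches, dHs):
    """Backpropagation through time; dHs (B, T, H) -> (dX, dWx, dWh, db)."""
    B, T, H = dHs.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.empty((B, T, Wx.shape[0]))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in reversed(range(T)):
        x_t, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
        dh = dHs[:, t] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
        )
        dWx += x_t.T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dX[:, t] = da @ Wx.T
        dh_next = da @ Wh.T
        dc_next = dc * f
    return dX, dWx, dWh, db


def lstm_forward(
    model: ClassifierModel,
    batch: np.ndarray,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
):
    """Forward pass over standardized sequences (B, T, 1) -> (probs, cache).

    Training mode uses batch statistics in the batch-norm step (updating
    the running averages) and applies inverted dropout; evaluation mode is
    fully deterministic, using the stored running statistics.
    """
    batch = np.asarray(batch, dtype=float)
    if not np.all(np.isfinite(batch)):
        raise ValidationError("non-finite values in classifier input")
    if batch.ndim != 3 or batch.shape[2] != 1:
        raise ValidationError("batch must have shape (B, T, 1)")
    p = model.params
    cfg = model.config
    eps = cfg.bn_eps

    H1, cache1 = _lstm_layer_forward(p["lstm1.Wx"], p["lstm1.Wh"], p["lstm1.b"], batch)

    if training_mode:
        mu = H1.mean(axis=0)  # (T, H)
        var = H1.var(axis=0)
        m = cfg.bn_momentum
        model.running_mean = m * model.running_mean + (1 - m) * mu
        model.running_var = m * model.running_var + (1 - m) * var
    else:
        mu, var = model.running_mean, model.running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (H1 - mu) * inv_std
    bn_out = p["bn.gamma"] * xhat + p["bn.beta"]

    if training_mode and cfg.dropout_rate > 0:
        if rng is None:
            raise ValidationError("training-mode forward with dropout needs an rng")
        mask = (rng.random(bn_out.shape) >= cfg.dropout_rate) / (1.0 - cfg.dropout_rate)
    else:
        mask = np.ones_like(bn_out)
    dropped = bn_out * mask

    H2, cache2 = _lstm_layer_forward(p["lstm2.Wx"], p["lstm2.Wh"], p["lstm2.b"], dropped)
    h_last = H2[:, -1]
    logits = h_last @ p["dense.W"] + p["dense.b"]
    logits = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(logits)
    probs = exp / exp.sum(axis=1, keepdims=True)
    cache = {
        "cache1": cache1,
        "cache2": cache2,
        "xhat": xhat,
        "inv_std": inv_std,
        "mask": mask,
        "h_last": h_last,
        "probs": probs,
        "T": batch.shape[1],
        "training": training_mode,
        "batch": batch,
    }
    return probs, cache


def _loss_from_probs(probs: np.ndarray, y: np.ndarray, params: dict, l2: float) -> float:
    ce = -np.mean(np.log(probs[np.arange(len(y)), y] + 1e-300))
    reg = l2 * sum(float(np.sum(params[k] ** 2)) for k in WEIGHT_KEYS)
    return float(ce + reg)


def lstm_gradients(model: ClassifierModel, cache: dict, labels: np.ndarray):
    """Exact gradients of cross-entropy + L2 for every parameter.

    Backpropagates through the dense head, layer-2 BPTT, dropout, batch
    normalization (including the dependence of batch statistics on the
    input when the cache was built in training mode) and layer-1 BPTT.
    """
    p = model.params
    cfg = model.config
    y = np.asarray(labels)
    B = len(y)
    probs = cache["probs"]

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B

    grads = {}
    grads["dense.W"] = cache["h_last"].T @ dlogits
    grads["dense.b"] = dlogits.sum(axis=0)
    dh_last = dlogits @ p["dense.W"].T

    T = cache["T"]
    H = cfg.hidden_units
    dH2 = np.zeros((B, T, H))
    dH2[:, -1] = dh_last
    d_dropped, dWx2, dWh2, db2 = _lstm_layer_backward(
        p["lstm2.Wx"], p["lstm2.Wh"], cache["cache2"], dH2
    )
    grads["lstm2.Wx"], grads["lstm2.Wh"], grads["lstm2.b"] = dWx2, dWh2, db2

    d_bn_out = d_dropped * cache["mask"]
    xhat, inv_std = cache["xhat"], cache["inv_std"]
    grads["bn.gamma"] = np.sum(d_bn_out * xhat, axis=(0, 1))
    grads["bn.beta"] = np.sum(d_bn_out, axis=(0, 1))
    dxhat = d_bn_out * p["bn.gamma"]
    if cache["training"]:
        n = B
        dH1 = (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * np.sum(dxhat * xhat, axis=0))
        )
    else:
        dH1 = dxhat * inv_std

    _, dWx1, dWh1, db1 = _lstm_layer_backward(p["lstm1.Wx"], p["lstm1.Wh"], cache["cache1"], dH1)
    grads["lstm1.Wx"], grads["lstm1.Wh"], grads["lstm1.b"] = dWx1, dWh1, db1

    for k in WEIGHT_KEYS:
        grads[k] = grads[k] + 2.0 * cfg.l2_penalty * p[k]
    return grads


# ---------------------------------------------------------------------------
# splitting, training, evaluation


def stratified_split(
    labels: Sequence,
    train_fraction: float = 0.8,
    seed: int = 0,
    groups: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint stratified train/test indices, reproducible from the seed.

    Class proportions are preserved to within one example.  With
    ``groups`` given (one group id per example, e.g. the physical sample a
    spectrum came from), whole groups go to one side, preventing leakage
    of sample identity across the split.
    """
    labels = np.asarray(labels)
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1); the test set may not be empty")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    if groups is None:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if idx.size < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 examples")
            perm = rng.permutation(idx)
            n_train = int(round(train_fraction * idx.size))
            n_train = min(max(n_train, 1), idx.size - 1)
            train.extend(perm[:n_train])
            test.extend(perm[n_train:])
    else:
        groups = np.asarray(groups)
        for cls in np.unique(labels):
            gset = np.unique(groups[labels == cls])
            if gset.size < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 groups")
            perm = rng.permutation(gset)
            n_train = int(round(train_fraction * gset.size))
            n_train = min(max(n_train, 1), gset.size - 1)
            train_groups = set(perm[:n_train])
            for i in np.flatnonzero(labels == cls):
                (train if groups[i] in train_groups else test).append(int(i))
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


@dataclass
class TrainReport:
    history: list = field(default_factory=list)  # per-epoch dicts
    test_accuracy: float = math.nan
    test_loss: float = math.nan
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None
    seed: int = 0
    best_epoch: int = -1
    stopped_early: bool = False


def _adam_update(params, grads, state, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    state["t"] += 1
    t = state["t"]
    for k, g in grads.items():
        state["m"][k] = beta1 * state["m"][k] + (1 - beta1) * g
        state["v"][k] = beta2 * state["v"][k] + (1 - beta2) * g * g
        m_hat = state["m"][k] / (1 - beta1**t)
        v_hat = state["v"][k] / (1 - beta2**t)
        params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)


def train_classifier(
    X: np.ndarray,
    labels: Sequence,
    config: LSTMConfig,
    groups: Sequence | None = None,
) -> tuple[ClassifierModel, TrainReport]:
    """Train on raw (n, T) spectra with string (or integer) labels.

    The 80/20 split is stratified over individual spectra by default, the
    protocol matching a plain train/test split over the 180 rows; pass
    ``groups`` to keep all measurements of one physical sample on the same
    side instead.  Inputs are standardized per frequency with
    training-set statistics only.  Early stopping restores the weights of
    the best held-out-loss epoch.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels).tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y = np.array([classes.index(l) for l in labels])

    train_idx, test_idx = stratified_split(
        labels, config.train_fraction, seed=config.seed, groups=groups
    )
    x_mean = X[train_idx].mean(axis=0)
    x_std = X[train_idx].std(axis=0)
    x_std = np.where(x_std < 1e-12, 1.0, x_std)

    T = X.shape[1]
    H = config.hidden_units
    rng = np.random.default_rng(config.seed)
    model = ClassifierModel(
        config=config,
        params=init_parameters(config, T, rng),
        running_mean=np.zeros((T, H)),
        running_var=np.ones((T, H)),
        x_mean=x_mean,
        x_std=x_std,
        classes=classes,
    )
    Xs = ((X - x_mean) / x_std)[:, :, None]

    adam = {"t": 0, "m": {k: np.zeros_like(v) for k, v in model.params.items()},
            "v": {k: np.zeros_like(v) for k, v in model.params.items()}}
    report = TrainReport(train_indices=train_idx, test_indices=test_idx, seed=config.seed)
    best_loss = math.inf
    best_state = None
    patience_left = config.patience

    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        epoch_hits = 0
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            xb, yb = Xs[batch_idx], y[batch_idx]
            probs, cache = lstm_forward(model, xb, training_mode=True, rng=rng)
            loss = _loss_from_probs(probs, yb, model.params, config.l2_penalty)
            if not math.isfinite(loss):
                raise TrainingError(f"training loss diverged at epoch {epoch}")
            grads = lstm_gradients(model, cache, yb)
            _adam_update(model.params, grads, adam, config.learning_rate)
            epoch_loss += loss * len(batch_idx)
            epoch_hits += int(np.sum(np.argmax(probs, axis=1) == yb))

        val_acc, val_loss = evaluate_classifier(model, X[test_idx], labels[test_idx])
        report.history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / len(order),
                "train_accuracy": epoch_hits / len(order),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_state = (
                copy.deepcopy(model.params),
                model.running_mean.copy(),
                model.running_var.copy(),
            )
            report.best_epoch = epoch
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                report.stopped_early = True
                break

    if best_state is not None:
        model.params, model.running_mean, model.running_var = best_state
    report.test_accuracy, report.test_loss = evaluate_classifier(
        model, X[test_idx], labels[test_idx]
    )
    return model, report


def evaluate_classifier(model: ClassifierModel, X: np.ndarray, labels: Sequence):
    """(accuracy, mean cross-entropy) on raw spectra, evaluation mode."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("test set must be non-empty")
    y = np.array([model.classes.index(l) for l in labels])
    probs = model.predict_proba(np.asarray(X, dtype=float))
    acc = float(np.mean(np.argmax(probs, axis=1) == y))
    loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-300)))
    return acc, loss


def spectrum_dataset(cohort, channel: str = "X"):
    """(X, labels, groups) matrix of thawing-range spectra from a cohort.

    One row per measurement taken on the 0-4 degC schedule (fresh
    references and next-day measurements excluded), columns the 36
    frequencies ascending; ``channel`` picks resistance or reactance.
    """
    if channel not in ("R", "X"):
        raise ValueError("channel must be 'R' or 'X'")
    rows, labels, groups = [], [], []
    for tr in sorted(cohort, key=lambda t: t.sample_id):
        for s in tr.thaw_samples:
            if s.temperature_C < -0.5:
                continue  # frozen-range extras are not part of the design
            rows.append(s.resistance_ohm if channel == "R" else s.reactance_ohm)
            labels.append(tr.treatment)
            groups.append(tr.sample_id)
    return np.asarray(rows, dtype=float), np.asarray(labels), np.asarray(groups)
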