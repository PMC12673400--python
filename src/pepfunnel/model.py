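"""Bidirectional recurrent next-residue model, implemented in numpy.

The model maps a fixed 34-residue integer context to a probability
distribution over the 20 canonical amino acids:

    P(x_t | x_{t-34..t-1}; theta) = softmax(W h + b)

where ``h`` is produced by stacked bidirectional LSTM layers — each layer
runs a forward and a backward LSTM over the one-hot-encoded context and
concatenates their per-position hidden states, ``h_t = [h_fwd_t; h_bwd_t]``
— followed by two ReLU dense layers and a softmax head.  Training minimises
categorical cross-entropy with Adam, in two phases: a *base* phase on
full-length proteins and a *finetune* phase that continues from the base
parameters on short peptides.

Everything (weight init, epoch shuffling, dropout masks) is driven by a
single integer seed, so identical (config, seed, data) reproduces identical
parameters and histories bit-for-bit on a given platform.  The
implementation is pure numpy with explicit backpropagation through time;
the network is small (~2M parameters at the default width) and trains on
CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from pepfunnel.seqio import TrainingWindow

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "BiLSTMNextResidue",
    "build_model",
    "train_phase",
    "next_distribution",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters of the next-residue model and its two-phase schedule."""

    window: int = 35                 # context = window - 1 residues
    recurrent_layers: int = 2
    recurrent_units: int = 256       # per direction
    dense_layers: int = 2
    dense_units: int = 128
    dropout: float = 0.2
    vocab: int = 20
    learning_rate: float = 1e-3
    epochs_base: int = 150
    epochs_finetune: int = 45
    batch_base: int = 30
    batch_finetune: int = 62
    rng_seed: int = 0
    early_stopping: bool = False
    patience: int = 10

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("recurrent_layers", "recurrent_units", "dense_layers",
                     "dense_units", "vocab", "batch_base", "batch_finetune"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs_base < 0 or self.epochs_finetune < 0:
            raise ValueError("epoch counts must be non-negative")

    @property
    def context_length(self) -> int:
        return self.window - 1


@dataclass
class TrainingHistory:
    """Per-epoch loss (nats/token) and running accuracy for one phase."""

    phase: str
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


# ---------------------------------------------------------------------------
# low-level LSTM machinery

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _init_lstm(rng: np.random.Generator, d_in: int, units: int) -> dict[str, np.ndarray]:
    b = np.zeros(4 * units)
    b[units:2 * units] = 1.0  # forget-gate bias
    return {
        "W": _glorot(rng, (d_in, 4 * units)),
        "U": _glorot(rng, (units, 4 * units)),
        "b": b,
    }


def _lstm_forward(p: dict[str, np.ndarray], x: np.ndarray):
    """Run one LSTM direction over x (B, T, D); returns (H_seq, cache)."""
    B, T, _ = x.shape
    units = p["U"].shape[0]
    h = np.zeros((B, units))
    c = np.zeros((B, units))
    H_seq = np.empty((B, T, units))
    cache = []
    for t in range(T):
        z = x[:, t] @ p["W"] + h @ p["U"] + p["b"]
        i = _sigmoid(z[:, :units])
        f = _sigmoid(z[:, units:2 * units])
        g = np.tanh(z[:, 2 * units:3 * units])
        o = _sigmoid(z[:, 3 * units:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache.append((x[:, t], h, c, i, f, g, o, tanh_c))
        h, c = h_new, c_new
        H_seq[:, t] = h
    return H_seq, cache


def _lstm_backward(p: dict[str, np.ndarray], cache, dH_seq: np.ndarray):
    """Backprop one direction; returns (dx (B,T,D), grads dict)."""
    B, T, units = dH_seq.shape
    dW = np.zeros_like(p["W"])
    dU = np.zeros_like(p["U"])
    db = np.zeros_like(p["b"])
    dx = np.empty((B, T, p["W"].shape[0]))
    dh_next = np.zeros((B, units))
    dc_next = np.zeros((B, units))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
        dh = dH_seq[:, t] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
            axis=1,
        )
        dW += x_t.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ p["W"].T
        dh_next = dz @ p["U"].T
    return dx, {"W": dW, "U": dU, "b": db}


# ---------------------------------------------------------------------------
# estimator

class BiLSTMNextResidue(BaseEstimator):
    """Stacked-BiLSTM next-residue classifier (sklearn-style estimator).

    Parameters mirror :class:`ModelConfig`.  ``fit(X, y)`` runs the base
    phase from fresh weights; :meth:`fine_tune` continues training with the
    fine-tuning schedule.  ``X`` is an int array of shape
    (n_windows, window - 1) with values in {0..vocab-1}; ``y`` is the
    integer identity of the following residue.

    Fitted attributes: ``weights_`` (name -> ndarray), ``history_`` (list of
    :class:`TrainingHistory`, one per completed phase).
    """

    def __init__(
        self,
        window: int = 35,
        recurrent_layers: int = 2,
        recurrent_units: int = 256,
        dense_layers: int = 2,
        dense_units: int = 128,
        dropout: float = 0.2,
        vocab: int = 20,
        learning_rate: float = 1e-3,
        epochs_base: int = 150,
        epochs_finetune: int = 45,
        batch_base: int = 30,
        batch_finetune: int = 62,
        rng_seed: int = 0,
        early_stopping: bool = False,
        patience: int = 10,
    ):
        self.window = window
        self.recurrent_layers = recurrent_layers
        self.recurrent_units = recurrent_units
        self.dense_layers = dense_layers
        self.dense_units = dense_units
        self.dropout = dropout
        self.vocab = vocab
        self.learning_rate = learning_rate
        self.epochs_base = epochs_base
        self.epochs_finetune = epochs_finetune
        self.batch_base = batch_base
        self.batch_finetune = batch_finetune
        self.rng_seed = rng_seed
        self.early_stopping = early_stopping
        self.patience = patience

    # -- configuration plumbing ------------------------------------------

    @classmethod
    def from_config(cls, config: ModelConfig) -> "BiLSTMNextResidue":
        return cls(**asdict(config))

    @property
    def config(self) -> ModelConfig:
        return ModelConfig(**{k: getattr(self, k) for k in asdict(ModelConfig()).keys()})

    @property
    def context_length(self) -> int:
        return self.window - 1

    # -- weights ----------------------------------------------------------

    def _ensure_initialized(self) -> None:
        if getattr(self, "weights_", None) is not None:
            return
        ModelConfig(**self.get_params())  # validate hyperparameters
        ss = np.random.SeedSequence(self.rng_seed)
        init_ss, train_ss = ss.spawn(2)
        rng = np.random.default_rng(init_ss)
        self._train_rng = np.random.default_rng(train_ss)
        w: dict[str, np.ndarray] = {}
        d_in = self.vocab
        for layer in range(self.recurrent_layers):
            for direction in ("f", "b"):
                p = _init_lstm(rng, d_in, self.recurrent_units)
                for k, v in p.items():
                    w[f"lstm{layer}_{direction}_{k}"] = v
            d_in = 2 * self.recurrent_units
        for layer in range(self.dense_layers):
            w[f"dense{layer}_W"] = _glorot(rng, (d_in, self.dense_units))
            w[f"dense{layer}_b"] = np.zeros(self.dense_units)
            d_in = self.dense_units
        w["out_W"] = _glorot(rng, (d_in, self.vocab))
        w["out_b"] = np.zeros(self.vocab)
        self.weights_ = w
        self.history_: list[TrainingHistory] = []
        self._adam_m = {k: np.zeros_like(v) for k, v in w.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in w.items()}
        self._adam_t = 0

    def _reset(self) -> None:
        self.weights_ = None
        self._ensure_initialized()

    # -- forward / backward ----------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2 or X.shape[1] != self.context_length:
            raise ValueError(
                f"context must have length {self.context_length}, got shape {X.shape}"
            )
        if X.size and (X.min() < 0 or X.max() >= self.vocab):
            raise ValueError(f"context tokens must lie in 0..{self.vocab - 1}")
        return X.astype(np.int64)

    def _forward(self, X: np.ndarray, training: bool):
        """Forward pass; returns (probs, cache or None)."""
        w = self.weights_
        B, T = X.shape
        x = np.zeros((B, T, self.vocab))
        x[np.arange(B)[:, None], np.arange(T)[None, :], X] = 1.0
        cache = {"X": X} if training else None
        inp = x
        H = self.recurrent_units
        for layer in range(self.recurrent_layers):
            pf = {k: w[f"lstm{layer}_f_{k}"] for k in ("W", "U", "b")}
            pb = {k: w[f"lstm{layer}_b_{k}"] for k in ("W", "U", "b")}
            Hf, cf = _lstm_forward(pf, inp)
            Hb_rev, cb = _lstm_forward(pb, inp[:, ::-1])
            Hb = Hb_rev[:, ::-1]
            out = np.concatenate([Hf, Hb], axis=2)
            last = layer == self.recurrent_layers - 1
            if training:
                cache[f"lstm{layer}"] = (cf, cb)
            if last:
                # summary vector: forward state at the final position,
                # backward state at the first (its last processed step)
                pooled = np.concatenate([Hf[:, -1], Hb[:, 0]], axis=1)
                if training and self.dropout > 0:
                    mask = (self._train_rng.random(pooled.shape) >= self.dropout) / (1 - self.dropout)
                    pooled = pooled * mask
                    cache["pool_mask"] = mask
                inp = pooled
            else:
                if training and self.dropout > 0:
                    mask = (self._train_rng.random(out.shape) >= self.dropout) / (1 - self.dropout)
                    out = out * mask
                    cache[f"drop{layer}"] = mask
                inp = out
        a = inp
        for layer in range(self.dense_layers):
            z = a @ w[f"dense{layer}_W"] + w[f"dense{layer}_b"]
            a_new = np.maximum(z, 0.0)
            if training:
                cache[f"dense{layer}"] = (a, a_new)
            a = a_new
        logits = a @ w["out_W"] + w["out_b"]
        logits -= logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        probs = ex / ex.sum(axis=1, keepdims=True)
        if training:
            cache["head_in"] = a
        return probs, cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache) -> dict[str, np.ndarray]:
        w = self.weights_
        B = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads["out_W"] = cache["head_in"].T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        da = dlogits @ w["out_W"].T
        for layer in range(self.dense_layers - 1, -1, -1):
            a_in, a_out = cache[f"dense{layer}"]
            dz = da * (a_out > 0)
            grads[f"dense{layer}_W"] = a_in.T @ dz
            grads[f"dense{layer}_b"] = dz.sum(axis=0)
            da = dz @ w[f"dense{layer}_W"].T
        H = self.recurrent_units
        T = cache["X"].shape[1]
        for layer in range(self.recurrent_layers - 1, -1, -1):
            cf, cb = cache[f"lstm{layer}"]
            last = layer == self.recurrent_layers - 1
            if last:
                if "pool_mask" in cache:
                    da = da * cache["pool_mask"]
                dHf = np.zeros((B, T, H))
                dHb = np.zeros((B, T, H))
                dHf[:, -1] = da[:, :H]
                dHb[:, 0] = da[:, H:]
            else:
                if f"drop{layer}" in cache:
                    da = da * cache[f"drop{layer}"]
                dHf = da[..., :H]
                dHb = da[..., H:]
            pf = {k: w[f"lstm{layer}_f_{k}"] for k in ("W", "U", "b")}
            pb = {k: w[f"lstm{layer}_b_{k}"] for k in ("W", "U", "b")}
            dx_f, gf = _lstm_backward(pf, cf, dHf)
            dx_b_rev, gb = _lstm_backward(pb, cb, dHb[:, ::-1])
            dx = dx_f + dx_b_rev[:, ::-1]
            for k, v in gf.items():
                grads[f"lstm{layer}_f_{k}"] = v
            for k, v in gb.items():
                grads[f"lstm{layer}_b_{k}"] = v
            da = dx
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-7
        self._adam_t += 1
        t = self._adam_t
        lr = self.learning_rate * np.sqrt(1 - b2 ** t) / (1 - b1 ** t)
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            self.weights_[k] -= lr * m / (np.sqrt(v) + eps)

    # -- training ---------------------------------------------------------

    def _train(self, X: np.ndarray, y: np.ndarray, epochs: int, batch_size: int, phase: str) -> TrainingHistory:
        history = TrainingHistory(phase=phase)
        if epochs == 0:
            self.history_.append(history)
            return history
        n = X.shape[0]
        if n == 0:
            raise ValueError("cannot train on an empty window set")
        best_loss = np.inf
        wait = 0
        for _ in range(epochs):
            order = self._train_rng.permutation(n)
            tot_loss = 0.0
            tot_correct = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                probs, cache = self._forward(X[idx], training=True)
                yb = y[idx]
                tot_loss -= np.log(np.clip(probs[np.arange(len(idx)), yb], 1e-12, None)).sum()
                tot_correct += int((probs.argmax(axis=1) == yb).sum())
                grads = self._backward(probs, yb, cache)
                self._adam_step(grads)
            epoch_loss = tot_loss / n
            history.loss.append(float(epoch_loss))
            history.accuracy.append(tot_correct / n)
            if self.early_stopping:
                if epoch_loss < best_loss - 1e-6:
                    best_loss = epoch_loss
                    wait = 0
                else:
                    wait += 1
                    if wait >= self.patience:
                        break
        self.history_.append(history)
        return history

    def fit(self, X, y) -> "BiLSTMNextResidue":
        """Base-phase training from freshly initialised weights."""
        X = self._validate_X(X)
        y = np.asarray(y, dtype=np.int64)
        self._reset()
        self._train(X, y, self.epochs_base, self.batch_base, phase="base")
        return self

    def fine_tune(self, X, y) -> "BiLSTMNextResidue":
        """Continue training from the current parameters on new windows."""
        if getattr(self, "weights_", None) is None:
            raise ValueError("fine_tune requires a fitted model; call fit first")
        X = self._validate_X(X)
        y = np.asarray(y, dtype=np.int64)
        self._train(X, y, self.epochs_finetune, self.batch_finetune, phase="finetune")
        return self

    # -- inference --------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Probability distribution over the 20 residues for each context."""
        self._ensure_initialized()
        X = self._validate_X(X)
        probs, _ = self._forward(X, training=False)
        return probs

    def predict(self, X) -> np.ndarray:
        """Most probable next residue (lowest index wins exact ties)."""
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y) -> float:
        """Inference-mode next-residue accuracy."""
        y = np.asarray(y, dtype=np.int64)
        return float((self.predict(X) == y).mean())

    def evaluate(self, X, y) -> float:
        """Inference-mode mean cross-entropy (nats per token)."""
        probs = self.predict_proba(X)
        y = np.asarray(y, dtype=np.int64)
        return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


# ---------------------------------------------------------------------------
# functional wrappers

def build_model(config: ModelConfig) -> BiLSTMNextResidue:
    """Instantiate an untrained model (weights initialised from the seed)."""
    model = BiLSTMNextResidue.from_config(config)
    model._ensure_initialized()
    return model


def _windows_to_arrays(windows: Sequence[TrainingWindow]) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray([w.context for w in windows], dtype=np.int64)
    y = np.asarray([w.target for w in windows], dtype=np.int64)
    return X, y


def train_phase(
    model: BiLSTMNextResidue,
    windows: Sequence[TrainingWindow],
    phase: str,
    config: ModelConfig | None = None,
) -> TrainingHistory:
    """Run one training phase (``"base"`` or ``"finetune"``) on window pairs."""
    if phase not in ("base", "finetune"):
        raise ValueError("phase must be 'base' or 'finetune'")
    cfg = config if config is not None else model.config
    epochs = cfg.epochs_base if phase == "base" else cfg.epochs_finetune
    batch = cfg.batch_base if phase == "base" else cfg.batch_finetune
    if not windows and epochs > 0:
        raise ValueError("cannot train on an empty window list")
    model._ensure_initialized()
    X, y = _windows_to_arrays(windows) if windows else (
        np.empty((0, model.context_length), dtype=np.int64),
        np.empty((0,), dtype=np.int64),
    )
    return model._train(X, y, epochs, batch, phase)


def next_distribution(model: BiLSTMNextResidue, context) -> np.ndarray:
    """Length-20 probability vector for a single 34-token context."""
    context = np.asarray(context)
    if context.ndim != 1:
        raise ValueError("context must be a 1-D token sequence")
    return model.predict_proba(context[None, :])[0]


# ---------------------------------------------------------------------------
# persistence

def save_checkpoint(model: BiLSTMNextResidue, path: str | Path) -> None:
    """Persist config, weights, optimiser state and history to one archive."""
    model._ensure_initialized()
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "history": [asdict(h) for h in model.history_],
        "adam_t": model._adam_t,
    }
    arrays = {f"w__{k}": v for k, v in model.weights_.items()}
    arrays.update({f"m__{k}": v for k, v in model._adam_m.items()})
    arrays.update({f"v__{k}": v for k, v in model._adam_v.items()})
    with open(path, "wb") as fh:
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> BiLSTMNextResidue:
    """Restore a model saved by :func:`save_checkpoint`."""
    try:
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta"]).decode())
    except Exception as exc:
        raise IOError(f"cannot read checkpoint {path}: {exc}") from exc
    if meta.get("version") != CHECKPOINT_VERSION:
        raise IOError(f"checkpoint version mismatch: {meta.get('version')}")
    config = ModelConfig(**meta["config"])
    model = BiLSTMNextResidue.from_config(config)
    model._ensure_initialized()
    for k in list(model.weights_):
        model.weights_[k] = data[f"w__{k}"]
        model._adam_m[k] = data[f"m__{k}"]
        model._adam_v[k] = data[f"v__{k}"]
    model._adam_t = meta["adam_t"]
    model.history_ = [TrainingHistory(**h) for h in meta["history"]]
    return model
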