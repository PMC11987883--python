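"""CLA-PTNet: continuous remaining-time-to-farrowing regression.

The network maps a fixed-length activity window (t points, 5-minute
resolution) to the remaining minutes until farrowing onset.  Pipeline:

* CBE — stacked length-preserving Conv1d + BatchNorm + ELU blocks that
  extract local activity features;
* LDE — an LSTM over the feature sequence (full hidden-state sequence kept),
  followed by ELU and dropout, capturing long-range temporal dependencies;
* PTW-SA — position-aware time-weighted self-attention over the hidden
  states (see :class:`farrowcast.nn.PTWSA`);
* head — mean pooling over time (or last-step pooling) into a fully
  connected layer producing the scalar prediction.

Inputs and labels are standardized internally with statistics computed from
the training set only; the statistics travel with the checkpoint so
prediction always returns minutes.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .datasets import WindowedSample

__all__ = ["ModelConfig", "EvalMetrics", "CLAPTNet", "train", "evaluate",
           "TrainHistory", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training settings.

    Defaults are deliberately small (single conv block, one 32-unit LSTM):
    the windows are univariate and desk-scale CPU training is the intended
    regime.  ``attention_scale`` selects the attention-score divisor:
    ``sqrt_d`` (standard scaled dot-product) or the literal ``d``.
    """

    seq_len: int = 72
    cbe_channels: tuple[int, ...] = (16,)
    cbe_kernel_sizes: tuple[int, ...] = (5,)
    lstm_hidden: int = 32
    lstm_layers: int = 1
    dropout: float = 0.2
    attention_scale: str = "sqrt_d"
    pooling: str = "mean"           # or "last"
    loss: str = "mse"               # or "mae"
    label_transform: str = "log1p"  # or "none"; log compresses the far range so
                                    # near-onset minutes dominate the loss
    learning_rate: float = 3e-3
    epochs: int = 60
    batch_size: int = 64
    patience: int = 12              # early stopping on validation MAE; 0 disables
    grad_clip: float = 1.0          # global gradient-norm ceiling; 0 disables
    seed: int = 0

    def validate(self) -> None:
        if self.seq_len < 1 or self.lstm_hidden < 1 or self.lstm_layers < 1:
            raise ValueError("seq_len, lstm_hidden and lstm_layers must be >= 1")
        if len(self.cbe_channels) != len(self.cbe_kernel_sizes) or not self.cbe_channels:
            raise ValueError("cbe_channels and cbe_kernel_sizes must be equal-length, non-empty")
        if any(k % 2 == 0 or k < 1 for k in self.cbe_kernel_sizes):
            raise ValueError("all CBE kernel sizes must be odd (length-preserving convolutions)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.pooling not in ("mean", "last"):
            raise ValueError(f"pooling must be 'mean' or 'last', got {self.pooling!r}")
        if self.loss not in ("mse", "mae"):
            raise ValueError(f"loss must be 'mse' or 'mae', got {self.loss!r}")
        if self.label_transform not in ("log1p", "none"):
            raise ValueError(f"label_transform must be 'log1p' or 'none', got {self.label_transform!r}")


@dataclass
class EvalMetrics:
    """Regression metrics in label units (minutes)."""

    mae: float
    rmse: float
    r2: float


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    best_epoch: int = -1


class CLAPTNet:
    """The assembled network plus its input/label scalers."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        init_rng, self.dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        layers: list[nn.Layer] = []
        c_prev = 1
        for c, k in zip(cfg.cbe_channels, cfg.cbe_kernel_sizes):
            layers += [nn.Conv1d(c_prev, c, k, init_rng), nn.BatchNorm1d(c), nn.ELU()]
            c_prev = c
        for li in range(cfg.lstm_layers):
            layers.append(nn.LSTM(c_prev, cfg.lstm_hidden, init_rng))
            c_prev = cfg.lstm_hidden
        layers += [nn.ELU(), nn.Dropout(cfg.dropout, self.dropout_rng)]
        self.attention = nn.PTWSA(cfg.seq_len, cfg.lstm_hidden, init_rng,
                                  scale_mode=cfg.attention_scale)
        layers.append(self.attention)
        layers.append(nn.MeanPoolTime() if cfg.pooling == "mean" else nn.LastStepPool())
        layers.append(nn.Linear(cfg.lstm_hidden, 1, init_rng))
        self.net = nn.Sequential(layers)
        # train-set scalers; identity until fit
        self.x_mean, self.x_sd = 0.0, 1.0
        self.y_mean, self.y_sd = 0.0, 1.0

    # -- basic plumbing ------------------------------------------------------

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def _prep(self, windows: np.ndarray) -> np.ndarray:
        x = np.asarray(windows, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.cfg.seq_len:
            raise ValueError(f"window length {x.shape[1]} != configured seq_len {self.cfg.seq_len}")
        return (x - self.x_mean) / self.x_sd

    def _transform_labels(self, y: np.ndarray) -> np.ndarray:
        return np.log1p(y) if self.cfg.label_transform == "log1p" else y

    def _inverse_labels(self, z: np.ndarray) -> np.ndarray:
        return np.expm1(z) if self.cfg.label_transform == "log1p" else z

    def forward(self, windows: np.ndarray, train: bool = False) -> np.ndarray:
        """Predict remaining minutes for a batch of windows (B, t)."""
        out = self.net.forward(self._prep(windows), train=train)[:, 0]
        return self._inverse_labels(out * self.y_sd + self.y_mean)

    def predict(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(windows, dtype=np.float64)
        if x.ndim == 1:
            return self.forward(x)
        return np.concatenate([
            self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
        ])

    # -- checkpoint state ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.net.layers):
            for k, v in layer.params.items():
                state[f"layer{i}.{k}"] = v.copy()
            if isinstance(layer, nn.BatchNorm1d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        state["scaler"] = np.array([self.x_mean, self.x_sd, self.y_mean, self.y_sd])
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.net.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i}.{k}"]
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]
        self.x_mean, self.x_sd, self.y_mean, self.y_sd = (float(v) for v in state["scaler"])


def _samples_to_arrays(samples: Sequence[WindowedSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.window for s in samples])
    y = np.array([float(s.label) for s in samples])
    return X, y


def evaluate(predictions: Sequence[float], labels: Sequence[float]) -> EvalMetrics:
    """MAE, RMSE and the coefficient of determination R^2.

    MAE = mean |y - yhat|; RMSE = sqrt(mean (y - yhat)^2); R^2 = 1 - SS_res /
    SS_tot.  R^2 can be arbitrarily negative for predictors worse than the
    label mean; it is undefined (raises) when all labels are equal.
    """
    yhat = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if yhat.shape != y.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("predictions and labels must be equal-length non-empty 1-D arrays")
    err = y - yhat
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined: all labels are identical")
    r2 = 1.0 - float((err**2).sum()) / ss_tot
    return EvalMetrics(mae=mae, rmse=rmse, r2=r2)


def train(
    model: CLAPTNet,
    train_samples: Sequence[WindowedSample],
    val_samples: Sequence[WindowedSample] | None = None,
    cfg: ModelConfig | None = None,
) -> TrainHistory:
    """Fit the model in place; returns per-epoch loss history.

    Seeded and reproducible: initialization, dropout and batch shuffling all
    derive from ``cfg.seed``.  When a validation set is given, the best
    parameters by validation MAE are restored at the end, with optional
    early stopping after ``cfg.patience`` non-improving epochs.
    """
    cfg = cfg or model.cfg
    if not train_samples:
        raise ValueError("training set is empty")
    X, y = _samples_to_arrays(train_samples)
    yt = model._transform_labels(y)
    # scalers from training data only (frozen for val/test/deployment)
    model.x_mean = float(X.mean())
    model.x_sd = float(X.std()) or 1.0
    model.y_mean = float(yt.mean())
    model.y_sd = float(yt.std()) or 1.0
    Xs = (X[:, :, None] - model.x_mean) / model.x_sd
    ys = (yt - model.y_mean) / model.y_sd

    shuffle_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(99,)))
    layers = model.net.parameter_layers()
    opt = nn.Adam(layers, lr=cfg.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0
    n = len(Xs)

    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = Xs[sel], ys[sel]
            model.net.zero_grads()
            pred = model.net.forward(xb, train=True)[:, 0]
            err = pred - yb
            if cfg.loss == "mse":
                loss = float((err**2).mean())
                dpred = 2.0 * err / len(err)
            else:
                loss = float(np.abs(err).mean())
                dpred = np.sign(err) / len(err)
            total += loss * len(err)
            model.net.backward(dpred[:, None])
            if cfg.grad_clip:
                gnorm = np.sqrt(sum(float((g**2).sum())
                                    for l in layers for g in l.grads.values()))
                if gnorm > cfg.grad_clip:
                    scale = cfg.grad_clip / gnorm
                    for l in layers:
                        for k in l.grads:
                            l.grads[k] *= scale
            opt.step()
        history.train_loss.append(total / n)

        if val_samples:
            Xv, yv = _samples_to_arrays(val_samples)
            val_mae = float(np.abs(model.predict(Xv) - yv).mean())
            history.val_mae.append(val_mae)
            if val_mae < best_val - 1e-9:
                best_val = val_mae
                best_state = model.state_dict()
                history.best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if cfg.patience and stale >= cfg.patience:
                    break

    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def save_checkpoint(path: str | Path, model: CLAPTNet) -> None:
    """Single-file checkpoint: config JSON plus all parameter arrays."""
    state = model.state_dict()
    cfg_json = json.dumps(asdict(model.cfg))
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> CLAPTNet:
    with np.load(path) as data:
        cfg_raw = json.loads(bytes(data["__config__"]).decode())
        for key in ("cbe_channels", "cbe_kernel_sizes"):
            cfg_raw[key] = tuple(cfg_raw[key])
        model = CLAPTNet(ModelConfig(**cfg_raw))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
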