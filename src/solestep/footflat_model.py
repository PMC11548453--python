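"""Windowed many-to-one recurrent foot-flat classifier.

At each labeled IMU sample the model consumes a short window of anterior
(past) samples of the retained channels and predicts the probability that
the foot is flat at the window's final sample — a causal, many-to-one
formulation.  The default configuration is the tuned operating point of
the method: 2 LSTM layers of 32 units, no intermediate dense layer, a
125 ms input window, dropout 0.2, tanh activation, learning rate 1e-2,
batch size 1024, trained with Adam on binary cross-entropy for up to 100
epochs with two early-stopping rules (patience 10 on validation loss and
a 5-minute wall-clock budget), restoring the best-validation weights.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._lstm import Adam, LSTMNet, bce_loss
from .recording_io import EnrichedRecording

__all__ = [
    "ModelConfig",
    "WindowedDataset",
    "make_windows",
    "WindowNormalizer",
    "fit_normalizer",
    "apply_normalizer",
    "FootFlatClassifier",
    "build_model",
    "train",
    "predict_status",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the recurrent foot-flat classifier.

    Defaults are the tuned operating point; :meth:`nominal` returns the
    untuned starting configuration (64 units, 50 ms window, dropout 0.4,
    learning rate 1e-3).
    """

    n_lstm_units: int = 32
    n_lstm_layers: int = 2
    dense_layer_active: bool = False
    n_dense_units: int = 32
    input_window_ms: float = 125.0
    dropout: float = 0.2
    lstm_activation: str = "tanh"
    learning_rate: float = 1e-2
    batch_size: int = 1024
    decision_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def nominal(cls) -> "ModelConfig":
        return cls(n_lstm_units=64, input_window_ms=50.0, dropout=0.4,
                   learning_rate=1e-3)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class WindowedDataset:
    """Fixed-length windows of retained channels, labeled at the final sample."""

    X: np.ndarray                 # (n, w, c) float32
    y: np.ndarray                 # (n,) int8, values {0,1}
    end_times: np.ndarray         # (n,) s
    channels: list[str]
    fs: float
    window_ms: float

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def window_samples(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(self.X[idx], self.y[idx], self.end_times[idx],
                               self.channels, self.fs, self.window_ms)

    @staticmethod
    def concatenate(datasets: list["WindowedDataset"]) -> "WindowedDataset":
        first = datasets[0]
        return WindowedDataset(
            np.concatenate([d.X for d in datasets]),
            np.concatenate([d.y for d in datasets]),
            np.concatenate([d.end_times for d in datasets]),
            first.channels, first.fs, first.window_ms)


def window_samples(window_ms: float, fs: float) -> int:
    """Window length in samples: round(window_ms × fs / 1000), at least 1."""
    w = int(round(window_ms * fs / 1000.0))
    if w < 1:
        raise ValueError(f"window of {window_ms} ms holds no sample at {fs} Hz")
    return w


def make_windows(enr: EnrichedRecording | pd.DataFrame, channels: list[str],
                 window_ms: float, fs: float | None = None,
                 stride: int = 1, include_undetermined: bool = False) -> WindowedDataset:
    """Slide windows of anterior data over an enriched recording.

    Windows end at samples w-1, w-1+stride, ...; a window whose final
    sample has undetermined status (2) is excluded by default (training
    and label metrics need determined endpoints), but undetermined
    samples may still appear *inside* retained windows — sensor data
    exists regardless of video visibility.  With
    ``include_undetermined=True`` every endpoint is kept (labels may then
    contain 2), which is how deployment-style prediction streams for step
    counting are built.
    """
    if isinstance(enr, EnrichedRecording):
        frame = enr.frame
        fs = enr.fs if fs is None else fs
    else:
        frame = enr
        if fs is None:
            raise ValueError("fs required when passing a bare DataFrame")
    missing = [c for c in channels if c not in frame.columns]
    if missing:
        raise ValueError(f"channels not in recording: {missing}")
    w = window_samples(window_ms, fs)
    n = len(frame)
    if w > n:
        raise ValueError(f"window of {w} samples exceeds recording length {n}")
    values = np.ascontiguousarray(frame[list(channels)].to_numpy(dtype=np.float32))
    status = frame["foot_status"].to_numpy()
    times = frame["time_s"].to_numpy()

    views = np.lib.stride_tricks.sliding_window_view(values, w, axis=0)  # (n-w+1, c, w)
    ends = np.arange(w - 1, n, stride)
    if not include_undetermined:
        ends = ends[status[ends] != 2]
    X = np.ascontiguousarray(views[ends - (w - 1)].transpose(0, 2, 1))
    return WindowedDataset(X, status[ends].astype(np.int8), times[ends],
                           list(channels), fs, window_ms)


class WindowNormalizer(BaseEstimator, TransformerMixin):
    """Per-channel z-scoring fitted on training windows only.

    Attributes
    ----------
    mean_, scale_ : (c,) arrays; a zero-variance channel gets scale 1.
    """

    def fit(self, X: np.ndarray | WindowedDataset, y=None) -> "WindowNormalizer":
        arr = X.X if isinstance(X, WindowedDataset) else np.asarray(X)
        self.mean_ = arr.mean(axis=(0, 1)).astype(np.float32)
        sd = arr.std(axis=(0, 1)).astype(np.float32)
        if np.any(sd < 1e-12):
            warnings.warn("zero-variance channel: scale clamped to 1", stacklevel=2)
            sd = np.where(sd < 1e-12, 1.0, sd).astype(np.float32)
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray | WindowedDataset):
        check_is_fitted(self, "mean_")
        if isinstance(X, WindowedDataset):
            Xn = ((X.X - self.mean_) / self.scale_).astype(np.float32)
            return WindowedDataset(Xn, X.y, X.end_times, X.channels, X.fs, X.window_ms)
        return ((np.asarray(X) - self.mean_) / self.scale_).astype(np.float32)


def fit_normalizer(train: WindowedDataset) -> WindowNormalizer:
    return WindowNormalizer().fit(train)


def apply_normalizer(ds: WindowedDataset, stats: WindowNormalizer) -> WindowedDataset:
    return stats.transform(ds)


class FootFlatClassifier(ClassifierMixin, BaseEstimator):
    """Stacked many-to-one LSTM binary classifier over sensor windows.

    Inputs are arrays of shape (n_windows, window_samples, n_channels);
    the positive class (1) is "foot flat".  See :class:`ModelConfig` for
    the meaning and defaults of the hyperparameters.

    Attributes (after fit)
    ----------------------
    net_ : the underlying network
    n_parameters_ : total trainable parameter count
    history_ : dict with per-epoch "loss", "val_loss", and "stop_reason"
    classes_ : array([0, 1])
    """

    def __init__(self, n_lstm_units: int = 32, n_lstm_layers: int = 2,
                 dense_layer_active: bool = False, n_dense_units: int = 32,
                 input_window_ms: float = 125.0, dropout: float = 0.2,
                 lstm_activation: str = "tanh", learning_rate: float = 1e-2,
                 batch_size: int = 1024, decision_threshold: float = 0.5,
                 epochs: int = 100, patience: int = 10, max_minutes: float = 5.0,
                 random_state: int = 0):
        self.n_lstm_units = n_lstm_units
        self.n_lstm_layers = n_lstm_layers
        self.dense_layer_active = dense_layer_active
        self.n_dense_units = n_dense_units
        self.input_window_ms = input_window_ms
        self.dropout = dropout
        self.lstm_activation = lstm_activation
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.decision_threshold = decision_threshold
        self.epochs = epochs
        self.patience = patience
        self.max_minutes = max_minutes
        self.random_state = random_state

    @classmethod
    def from_config(cls, cfg: ModelConfig, **kwargs) -> "FootFlatClassifier":
        return cls(n_lstm_units=cfg.n_lstm_units, n_lstm_layers=cfg.n_lstm_layers,
                   dense_layer_active=cfg.dense_layer_active,
                   n_dense_units=cfg.n_dense_units,
                   input_window_ms=cfg.input_window_ms, dropout=cfg.dropout,
                   lstm_activation=cfg.lstm_activation,
                   learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                   decision_threshold=cfg.decision_threshold,
                   random_state=cfg.seed, **kwargs)

    # ------------------------------------------------------------------ build
    def build(self, n_channels: int) -> "FootFlatClassifier":
        """Initialize the network for a given channel count (idempotent in fit)."""
        self.net_ = LSTMNet(
            n_channels=n_channels, n_units=self.n_lstm_units,
            n_layers=self.n_lstm_layers, dense_active=self.dense_layer_active,
            n_dense_units=self.n_dense_units, activation=self.lstm_activation,
            dropout=self.dropout, seed=self.random_state)
        self.n_parameters_ = self.net_.n_parameters
        self.n_channels_ = n_channels
        self.classes_ = np.array([0, 1])
        return self

    # -------------------------------------------------------------------- fit
    def fit(self, X: np.ndarray, y: np.ndarray,
            validation_data: tuple[np.ndarray, np.ndarray] | None = None
            ) -> "FootFlatClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError(f"X must be (n, window, channels), got shape {X.shape}")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        y = y.astype(np.float32)
        self.build(X.shape[2])
        net = self.net_
        opt = Adam(net.params, lr=self.learning_rate)
        rng = np.random.default_rng(self.random_state)

        has_val = validation_data is not None
        if has_val:
            Xv = np.asarray(validation_data[0], dtype=np.float32)
            yv = np.asarray(validation_data[1], dtype=np.float32)
            if Xv.shape[0] == 0:
                raise ValueError("empty validation set")

        n = X.shape[0]
        B = min(self.batch_size, n)
        best_loss = np.inf
        best_params = None
        best_epoch = -1
        history: dict = {"loss": [], "val_loss": [] if has_val else None}
        t_start = time.monotonic()
        stop_reason = "epochs"
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            timed_out = False
            for start in range(0, n, B):
                idx = order[start:start + B]
                p, cache = net.forward(X[idx], training=True, rng=rng)
                losses.append(bce_loss(p, y[idx]) * idx.size)
                grads = net.backward(X[idx], p, y[idx], cache)
                opt.step(net.params, grads)
                if (time.monotonic() - t_start) / 60.0 >= self.max_minutes:
                    timed_out = True
                    break
            history["loss"].append(float(np.sum(losses) / n))
            monitor = history["loss"][-1]
            if has_val:
                pv = self._forward_batched(Xv)
                vloss = bce_loss(pv, yv)
                history["val_loss"].append(vloss)
                monitor = vloss
            if monitor < best_loss:
                best_loss = monitor
                best_params = {k: v.copy() for k, v in net.params.items()}
                best_epoch = epoch
            if timed_out:
                stop_reason = "time"
                break
            if epoch - best_epoch >= self.patience:
                stop_reason = "patience"
                break
        if best_params is not None:
            net.params = best_params
        history["stop_reason"] = stop_reason
        history["best_epoch"] = best_epoch
        history["best_loss"] = float(best_loss)
        self.history_ = history
        return self

    def _forward_batched(self, X: np.ndarray, batch: int = 4096) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=np.float32)
        for start in range(0, X.shape[0], batch):
            p, _ = self.net_.forward(X[start:start + batch], training=False)
            out[start:start + batch] = p
        return out

    # ---------------------------------------------------------------- predict
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[2] != self.n_channels_:
            raise ValueError(
                f"channel mismatch: expected (n, w, {self.n_channels_}) input, "
                f"got shape {X.shape}")
        p1 = self._forward_batched(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary foot status: 1 iff P(flat) >= decision_threshold."""
        p = self.predict_proba(X)[:, 1]
        return (p >= self.decision_threshold).astype(np.int8)


    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        """Checkpoint weights plus the embedded JSON config to an .npz file."""
        check_is_fitted(self, "net_")
        import json

        meta = {"config": ModelConfig(
            n_lstm_units=self.n_lstm_units, n_lstm_layers=self.n_lstm_layers,
            dense_layer_active=self.dense_layer_active,
            n_dense_units=self.n_dense_units,
            input_window_ms=self.input_window_ms, dropout=self.dropout,
            lstm_activation=self.lstm_activation,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            decision_threshold=self.decision_threshold,
            seed=self.random_state).to_dict(),
            "n_channels": self.n_channels_}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.net_.params)

    @classmethod
    def load(cls, path) -> "FootFlatClassifier":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        clf = cls.from_config(ModelConfig.from_dict(meta["config"]))
        clf.build(meta["n_channels"])
        clf.net_.params = params
        return clf


def build_model(cfg: ModelConfig, n_channels: int) -> FootFlatClassifier:
    """Instantiate and initialize the classifier for a channel count."""
    return FootFlatClassifier.from_config(cfg).build(n_channels)


def train(model: FootFlatClassifier, train_ds: WindowedDataset,
          val_ds: WindowedDataset | None = None, epochs: int = 100,
          patience: int = 10, max_minutes: float = 5.0) -> FootFlatClassifier:
    """Fit on a windowed dataset with the standard early-stopping rules."""
    model.set_params(epochs=epochs, patience=patience, max_minutes=max_minutes)
    val = (val_ds.X, val_ds.y) if val_ds is not None else None
    return model.fit(train_ds.X, train_ds.y, validation_data=val)


def predict_status(model: FootFlatClassifier, ds: WindowedDataset,
                   decision_threshold: float | None = None) -> np.ndarray:
    """Binary foot-status stream aligned to the dataset's window end times."""
    if ds.channels and len(ds.channels) != model.n_channels_:
        raise ValueError(
            f"channel mismatch: model expects {model.n_channels_}, "
            f"dataset has {len(ds.channels)}")
    p = model.predict_proba(ds.X)[:, 1]
    thr = model.decision_threshold if decision_threshold is None else decision_threshold
    return (p >= thr).astype(np.int8)
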