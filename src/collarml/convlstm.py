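"""Convolutional LSTM state classifier.

Architecture (defaults, all configurable): a stack of four 1-D
convolutions (width 64, kernel 5, ReLU, valid padding) feeding two LSTM
layers (hidden 128), with the final hidden state passed to a dense
softmax layer sized to the label vocabulary (10 or 50 nodes).  A
larger-capacity variant uses convolution width 1024.  Input is a batch
of fused sensor sequences of identical shape (T x C); the channel count
is read from the data, never hard-coded.

Training is mini-batch Adam on softmax cross-entropy, with a stratified
validation split carved from the training set and optional early
stopping on validation loss.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn


class ConfigurationError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class ConvLSTMConfig:
    conv_width: int = 64            # 1024 for the high-capacity variant
    conv_kernel: int = 5
    n_conv_layers: int = 4
    pool: int = 1                   # optional time pooling after the convs
    lstm_hidden: int = 128
    n_lstm_layers: int = 2
    dense_out: int = 10             # must equal the vocabulary size
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    val_fraction: float = 0.1
    early_stopping_patience: int | None = 25
    seed: int = 0


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame(asdict(self)).to_csv(path, index_label="epoch")


def _build_network(T: int, C: int, config: ConvLSTMConfig,
                   rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    ch = C
    t = T
    for _ in range(config.n_conv_layers):
        if t < config.conv_kernel:
            raise ConfigurationError(
                f"sequence too short ({t}) for kernel {config.conv_kernel}")
        layers += [nn.Conv1D(ch, config.conv_width, config.conv_kernel, rng=rng),
                   nn.ReLU()]
        ch = config.conv_width
        t -= config.conv_kernel - 1
    if config.pool > 1:
        t -= t % config.pool
        layers.append(_TruncatePool(config.pool))
        t //= config.pool
    for i in range(config.n_lstm_layers):
        last = i == config.n_lstm_layers - 1
        layers.append(nn.LSTM(ch, config.lstm_hidden,
                              return_sequences=not last, rng=rng))
        ch = config.lstm_hidden
    layers.append(nn.Dense(config.lstm_hidden, config.dense_out, rng=rng))
    return nn.Sequential(layers)


class _TruncatePool(nn.MaxPool1D):
    """Max pool that drops a trailing remainder instead of erroring."""

    def forward(self, x):
        T = x.shape[1]
        self._trim = T % self.pool
        if self._trim:
            x = x[:, :T - self._trim, :]
        return super().forward(x)

    def backward(self, dout):
        dx = super().backward(dout)
        if self._trim:
            dx = np.pad(dx, ((0, 0), (0, self._trim), (0, 0)))
        return dx


def _stratified_val_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_val = max(1, int(round(len(idx) * frac))) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


class ConvLSTMClassifier:
    """Conv-LSTM model object; ``fit()`` returns :class:`ConvLSTMResults`."""

    def __init__(self, X: np.ndarray, y: np.ndarray, vocabulary: list[str],
                 config: ConvLSTMConfig | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise DataError(f"expected (n, T, C) samples, got shape {X.shape}")
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise DataError("X/y length mismatch")
        config = config or ConvLSTMConfig()
        if config.dense_out != len(vocabulary):
            raise ConfigurationError(
                f"dense_out={config.dense_out} != vocabulary size {len(vocabulary)}")
        if y.min() < 0 or y.max() >= len(vocabulary):
            raise DataError("labels outside vocabulary range")
        self.X, self.y = X, y
        self.vocabulary = list(vocabulary)
        self.config = config

    @classmethod
    def from_split(cls, split, config: ConvLSTMConfig | None = None):
        X, y = split.arrays("train")
        config = config or ConvLSTMConfig(dense_out=len(split.vocabulary))
        return cls(X, y, split.vocabulary, config)

    def fit(self) -> "ConvLSTMResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n, T, C = self.X.shape
        net = _build_network(T, C, cfg, rng)
        opt = nn.Adam(net, lr=cfg.learning_rate)
        tr_idx, va_idx = _stratified_val_split(self.y, cfg.val_fraction, rng)
        Xtr, ytr = self.X[tr_idx], self.y[tr_idx]
        Xva, yva = self.X[va_idx], self.y[va_idx]
        history = TrainingHistory()
        best_val = np.inf
        best_state = None
        stale = 0
        t0 = time.perf_counter()
        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(Xtr))
            losses, correct = [], 0
            for start in range(0, len(Xtr), cfg.batch_size):
                b = order[start:start + cfg.batch_size]
                logits = net.forward(Xtr[b])
                loss, dlogits, probs = nn.softmax_cross_entropy(logits, ytr[b])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {_epoch}; lr={cfg.learning_rate}, "
                        f"batch={start // cfg.batch_size}: aborting")
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
                correct += int((probs.argmax(axis=1) == ytr[b]).sum())
            history.train_loss.append(float(np.mean(losses)))
            history.train_accuracy.append(correct / len(Xtr))
            if len(Xva):
                logits = net.forward(Xva)
                vloss, _, vprobs = nn.softmax_cross_entropy(logits, yva)
                vacc = float(np.mean(vprobs.argmax(axis=1) == yva))
            else:
                vloss, vacc = float("nan"), float("nan")
            history.val_loss.append(float(vloss))
            history.val_accuracy.append(vacc)
            if cfg.early_stopping_patience is not None and len(Xva):
                if vloss < best_val - 1e-12:
                    best_val, stale = vloss, 0
                    best_state = {k: v.copy() for k, v in net.state_arrays().items()}
                else:
                    stale += 1
                    if stale > cfg.early_stopping_patience:
                        break
        if best_state is not None:
            net.load_state_arrays(best_state)
        fit_seconds = time.perf_counter() - t0
        return ConvLSTMResults(model=self, network=net, history=history,
                               fit_seconds=fit_seconds,
                               input_shape=(T, C))


@dataclass
class ConvLSTMResults:
    model: ConvLSTMClassifier
    network: nn.Sequential
    history: TrainingHistory
    fit_seconds: float
    input_shape: tuple[int, int]

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise DataError(
                f"sample shape {X.shape[1:]} != training shape {self.input_shape}")
        out = []
        for start in range(0, len(X), batch_size):
            out.append(nn.softmax(self.network.forward(X[start:start + batch_size])))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.array([self.model.vocabulary[i] for i in probs.argmax(axis=1)])

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict_indices(X) == np.asarray(y)))

    @property
    def final_train_accuracy(self) -> float:
        return self.history.train_accuracy[-1]

    @property
    def final_val_accuracy(self) -> float:
        return self.history.val_accuracy[-1]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Conv-LSTM classification results",
            "================================",
            f"input shape           {self.input_shape[0]} x {self.input_shape[1]}",
            f"conv layers           {cfg.n_conv_layers} x width {cfg.conv_width} (kernel {cfg.conv_kernel})",
            f"lstm layers           {cfg.n_lstm_layers} x hidden {cfg.lstm_hidden}",
            f"output classes        {cfg.dense_out}",
            f"epochs run            {len(self.history.train_loss)} / {cfg.epochs}",
            f"final train loss      {self.history.train_loss[-1]:.4f}",
            f"final train accuracy  {self.final_train_accuracy:.4f}",
            f"final val accuracy    {self.final_val_accuracy:.4f}",
            f"fit wall time         {self.fit_seconds:.1f} s",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Checkpoint as .npz arrays plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.network.state_arrays())
        meta = {"config": asdict(self.model.config),
                "vocabulary": self.model.vocabulary,
                "input_shape": list(self.input_shape)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def train_convlstm(split, config: ConvLSTMConfig | None = None):
    """Functional wrapper: returns (results, history)."""
    results = ConvLSTMClassifier.from_split(split, config).fit()
    return results, results.history


def predict_convlstm(results: ConvLSTMResults, samples: np.ndarray):
    """Functional wrapper: returns (labels, class scores)."""
    probs = results.predict_proba(np.asarray(samples, dtype=float))
    labels = np.array([results.model.vocabulary[i] for i in probs.argmax(axis=1)])
    return labels, probs
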