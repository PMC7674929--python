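"""The interictal-preictal CNN: declarative architecture, exact parameter
accounting, RMSProp training with early stopping, and the four evaluation
metrics.

Architecture (fixed by the protocol): three convolution blocks of 64 feature
maps — an n×5×5 kernel with stride 2 (the n EEG channels enter as input
depth), then two 3×3 kernels with stride 1 — each followed by batch
normalization, ReLU and 2×2 max pooling, all unpadded ("valid"); then a
256-unit fully-connected layer with ReLU and dropout 0.5, and a single
sigmoid output unit.  Preictal is the positive class.

Training: RMSProp (lr 5e-4, momentum 0.9, weight decay 1e-6), binary
cross-entropy, He initialization, early stopping on validation loss with
best-weight restoration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .annotations import ConfigurationError
from .layers import (
    BatchNorm2d, Conv2d, Dropout, Flatten, Linear, MaxPool2x2, RMSProp, ReLU,
    bce_with_logits,
)
from .signal_prep import freq_mask

__all__ = [
    "ConvBlock", "ArchitectureSpec", "TrainingConfig", "EvalMetrics",
    "CNNModel", "TrainingDivergedError",
    "build_architecture", "spatial_trace", "count_parameters",
    "train_model", "evaluate",
]

N_MAPS = 64
FC1_OUT = 256
DROPOUT_P = 0.5
INPUT_T = 59


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; carries the history collected so far."""

    def __init__(self, message: str, history: dict):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class ConvBlock:
    out_maps: int
    kernel: tuple[int, int]
    stride: int
    batch_norm: bool = True
    pool: tuple[int, int] = (2, 2)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative layer list; the single source for model building and the
    closed-form trainable-parameter count."""

    n_channels: int
    input_T: int
    input_F: int
    conv_blocks: tuple[ConvBlock, ...]
    fc1_out: int = FC1_OUT
    fc2_out: int = 1
    dropout_p: float = DROPOUT_P


def build_architecture(n_channels: int, fs_out: int) -> ArchitectureSpec:
    """The protocol's CNN for n channels at a given output rate.

    input_F follows the rate's retained-bin rule (65 at 128 Hz, 81 at
    256/512 Hz).
    """
    if n_channels < 1:
        raise ConfigurationError("need at least one channel")
    spec = ArchitectureSpec(
        n_channels=n_channels,
        input_T=INPUT_T,
        input_F=int(freq_mask(fs_out).size),
        conv_blocks=(
            ConvBlock(N_MAPS, (5, 5), 2),
            ConvBlock(N_MAPS, (3, 3), 1),
            ConvBlock(N_MAPS, (3, 3), 1),
        ),
    )
    for t, f in spatial_trace(spec):
        if t < 1 or f < 1:
            raise ConfigurationError("spatial dimensions collapse to zero")
    return spec


def spatial_trace(spec: ArchitectureSpec) -> list[tuple[int, int]]:
    """(T, F) after each conv and each pool: valid-convolution dimension
    arithmetic floor((d - k)/s) + 1, pooling floor(d/2)."""
    dims = (spec.input_T, spec.input_F)
    trace = []
    for blk in spec.conv_blocks:
        dims = tuple((d - k) // blk.stride + 1 for d, k in zip(dims, blk.kernel))
        trace.append(dims)
        dims = tuple(d // p for d, p in zip(dims, blk.pool))
        trace.append(dims)
    return trace


def count_parameters(spec: ArchitectureSpec) -> int:
    """Closed-form trainable-parameter count.

    Convolutions: out*(in*kh*kw) + out biases; batch norm: 2*out (gamma,
    beta; running statistics are not trainable); FC1: flatten*fc1 + fc1;
    FC2: fc1*fc2 + fc2.
    """
    total = 0
    in_depth = spec.n_channels
    for blk in spec.conv_blocks:
        kh, kw = blk.kernel
        total += blk.out_maps * in_depth * kh * kw + blk.out_maps
        if blk.batch_norm:
            total += 2 * blk.out_maps
        in_depth = blk.out_maps
    ft, ff = spatial_trace(spec)[-1]
    flat = in_depth * ft * ff
    total += flat * spec.fc1_out + spec.fc1_out
    total += spec.fc1_out * spec.fc2_out + spec.fc2_out
    return total


@dataclass
class TrainingConfig:
    """Optimizer and loop settings; the three optimizer constants are the
    protocol's and stay fixed in protocol-faithful runs."""

    learning_rate: float = 5e-4
    momentum: float = 0.9
    weight_decay: float = 1e-6
    rms_alpha: float = 0.99
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    threshold: float = 0.5


@dataclass
class EvalMetrics:
    """Accuracy, F1, precision, recall as fractions; undefined ratios (e.g.
    precision with no positive predictions) are None, never silently 0."""

    accuracy: float
    f1: float | None
    precision: float | None
    recall: float | None

    def as_percent(self) -> dict:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in self.__dict__.items()
        }


class CNNModel:
    """An instantiated network built from an ArchitectureSpec."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        layers = []
        in_depth = spec.n_channels
        for blk in spec.conv_blocks:
            layers.append(Conv2d(in_depth, blk.out_maps, blk.kernel, blk.stride, rng, dtype))
            if blk.batch_norm:
                layers.append(BatchNorm2d(blk.out_maps, dtype=dtype))
            layers.append(ReLU())
            layers.append(MaxPool2x2())
            in_depth = blk.out_maps
        ft, ff = spatial_trace(spec)[-1]
        layers.append(Flatten())
        layers.append(Linear(in_depth * ft * ff, spec.fc1_out, rng, dtype))
        layers.append(ReLU())
        layers.append(Dropout(spec.dropout_p, rng))
        layers.append(Linear(spec.fc1_out, spec.fc2_out, rng, dtype))
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def num_parameters(self) -> int:
        """Parameter count by enumerating instantiated weight arrays."""
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=self.dtype)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for i in range(0, x.shape[0], batch_size):
            z = self.forward(x[i : i + batch_size], train=False).ravel()
            probs.append(1.0 / (1.0 + np.exp(-z.astype(np.float64))))
        return np.concatenate(probs) if probs else np.empty(0)

    def state_dict(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        state = copy.deepcopy(state)
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        rest = iter(state[len(ps):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = next(rest)
                layer.running_var[...] = next(rest)


def _epoch_loss(model: CNNModel, X: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, X.shape[0], batch_size):
        z = model.forward(X[i : i + batch_size], train=False)
        loss, _ = bce_with_logits(z, y[i : i + batch_size])
        total += loss * z.shape[0]
        n += z.shape[0]
    return total / max(n, 1)


def train_model(
    spec: ArchitectureSpec,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig,
) -> tuple[CNNModel, dict]:
    """Fit the CNN with mini-batch RMSProp and early stopping.

    Stops when the validation loss has not improved for ``config.patience``
    consecutive epochs (patience 0: stop at the first non-improving epoch) or
    at ``max_epochs``; the returned model carries the best-validation-loss
    weights.  History holds per-epoch train/val losses.
    """
    Xtr, ytr = train_set
    Xval, yval = val_set
    if Xtr.shape[0] == 0 or Xval.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")
    model = CNNModel(spec, seed=config.seed)
    opt = RMSProp(model.params(), lr=config.learning_rate, alpha=config.rms_alpha,
                  momentum=config.momentum, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    history: dict = {"train_loss": [], "val_loss": [], "stopped_epoch": None}
    best_loss = np.inf
    best_state = model.state_dict()
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(Xtr.shape[0])
        running, seen = 0.0, 0
        for i in range(0, order.size, config.batch_size):
            idx = order[i : i + config.batch_size]
            z = model.forward(Xtr[idx], train=True)
            loss, dz = bce_with_logits(z, ytr[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"loss became {loss} at epoch {epoch}", history)
            model.backward(dz)
            opt.step()
            running += loss * idx.size
            seen += idx.size
        val_loss = _epoch_loss(model, Xval, yval, config.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(f"validation loss became {val_loss}", history)
        history["train_loss"].append(running / seen)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                history["stopped_epoch"] = epoch
                break
    model.load_state_dict(best_state)
    history["best_val_loss"] = float(best_loss)
    return model, history


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def evaluate(model: CNNModel, test_set: tuple[np.ndarray, np.ndarray],
             threshold: float = 0.5) -> EvalMetrics:
    """Accuracy/F1/precision/recall on a test set; preictal (1) is positive."""
    X, y = test_set
    if X.shape[0] == 0:
        raise ValueError("test set must be non-empty")
    pred = (model.predict_proba(X) >= threshold).astype(int)
    y = np.asarray(y).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalMetrics(
        accuracy=(tp + tn) / y.size,
        f1=f1,
        precision=precision,
        recall=recall,
    )
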