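"""1D convolutional classifier with spatial attention.

Architecture: n_conv_blocks of [same-padded conv (16 channels, kernel 3) ->
batch norm -> ReLU -> max pool (2)] over the expression vector treated as a
length-``in_length`` single-channel signal, then a sigmoid spatial-attention
gate, dropout, flatten, one hidden fully-connected layer and a linear head
producing one logit per class. Trained with softmax cross-entropy under
Adam (lr 1e-3, batch 16) with early stopping on a stratified internal
validation split; the best-validation-loss parameters are returned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import train_test_split

from txclass._random import substream, subseed
from txclass.containers import DataError, ExpressionMatrix
from txclass.nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    Dropout,
    Flatten,
    Linear,
    MaxPool1d,
    ReLU,
    Sequential,
    SpatialAttention,
    cross_entropy,
    softmax,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CNNConfig:
    in_length: int = 2960
    conv_channels: int = 16
    kernel_size: int = 3
    n_conv_blocks: int = 3
    pool: int = 2
    attention_kernel: int = 7
    dropout_rate: float = 0.5
    n_classes: int = 3
    fc_hidden: int = 64

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0 or self.attention_kernel % 2 == 0:
            raise DataError("kernel sizes must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise DataError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise DataError("n_classes must be >= 2")
        if self.in_length < self.kernel_size:
            raise DataError("in_length must be >= kernel_size")
        length = self.in_length
        for _ in range(self.n_conv_blocks):
            length //= self.pool
        if length == 0:
            raise DataError(
                f"in_length {self.in_length} collapses to 0 after "
                f"{self.n_conv_blocks} pools; minimum length is {self.pool ** self.n_conv_blocks}"
            )

    @property
    def flat_length(self) -> int:
        length = self.in_length
        for _ in range(self.n_conv_blocks):
            length //= self.pool
        return length * self.conv_channels


@dataclass(frozen=True)
class ClassifierTrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.patience) <= 0:
            raise DataError("learning_rate, batch_size, patience must be positive")
        if self.max_epochs < 0:
            raise DataError("max_epochs must be >= 0")
        if not 0.0 < self.val_fraction <= 0.5:
            raise DataError("val_fraction must lie in (0, 0.5]")


@dataclass
class CNNModel:
    """A built (possibly trained) classifier with its label vocabulary."""

    cfg: CNNConfig
    net: Sequential
    classes: list[str] = field(default_factory=list)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.cfg.in_length:
            raise DataError(
                f"input width {x.shape[-1]} does not match in_length {self.cfg.in_length}"
            )
        return self.net.forward(x[:, None, :], train)


def build_model(cfg: CNNConfig, seed: int = 0) -> CNNModel:
    """Deterministically initialize the architecture for ``cfg``."""
    rng = substream(seed, "cnn_init")
    layers = []
    c_in = 1
    for _ in range(cfg.n_conv_blocks):
        layers.append(Conv1d(c_in, cfg.conv_channels, cfg.kernel_size, rng))
        layers.append(BatchNorm1d(cfg.conv_channels))
        layers.append(ReLU())
        layers.append(MaxPool1d(cfg.pool))
        c_in = cfg.conv_channels
    layers.append(SpatialAttention(cfg.attention_kernel, rng))
    layers.append(Dropout(cfg.dropout_rate, substream(seed, "cnn_dropout")))
    layers.append(Flatten())
    layers.append(Linear(cfg.flat_length, cfg.fc_hidden, rng))
    layers.append(ReLU())
    layers.append(Linear(cfg.fc_hidden, cfg.n_classes, rng))
    return CNNModel(cfg, Sequential(layers))


def train_classifier(
    train: ExpressionMatrix,
    cnn_cfg: CNNConfig | None = None,
    train_cfg: ClassifierTrainConfig = ClassifierTrainConfig(),
) -> tuple[CNNModel, list[dict]]:
    """Fit the classifier with early stopping; returns (model, history).

    An internal stratified fit/validation split (``val_fraction``) monitors
    the cross-entropy; training stops when the validation loss has not
    improved for ``patience`` epochs and the best-validation parameters are
    restored. History rows carry per-epoch train and validation loss.
    """
    classes = sorted(set(train.labels))
    if len(classes) < 2:
        raise DataError("training data must contain >= 2 classes")
    if cnn_cfg is None:
        cnn_cfg = CNNConfig(in_length=train.n_features, n_classes=len(classes))
    y = np.array([classes.index(c) for c in train.labels])
    x = train.values

    model = build_model(cnn_cfg, train_cfg.seed)
    model.classes = classes
    if train_cfg.max_epochs == 0:
        return model, []

    idx_fit, idx_val = train_test_split(
        np.arange(len(y)),
        test_size=train_cfg.val_fraction,
        stratify=y,
        random_state=subseed(train_cfg.seed, "cnn_split"),
    )
    if len(set(y[idx_fit])) < len(classes):
        raise DataError("a class is absent from the fit split; more samples needed")
    opt = Adam(model.net.params(), train_cfg.learning_rate)
    rng = substream(train_cfg.seed, "cnn_batches")

    best_val = np.inf
    best_state = None
    stale = 0
    history: list[dict] = []
    for epoch in range(train_cfg.max_epochs):
        perm = rng.permutation(idx_fit)
        batch_losses = []
        for start in range(0, len(perm), train_cfg.batch_size):
            batch = perm[start : start + train_cfg.batch_size]
            logits = model.forward_logits(x[batch], train=True)
            loss, dlogits = cross_entropy(logits, y[batch])
            model.net.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            batch_losses.append(loss)
        val_logits = model.forward_logits(x[idx_val], train=False)
        val_loss, _ = cross_entropy(val_logits, y[idx_val])
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)),
                "val_loss": float(val_loss),
            }
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [a.copy() for a in model.net.state_arrays()]
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.patience:
                log.info("early stop at epoch %d (best val loss %.4f)", epoch, best_val)
                break
    if best_state is not None:
        model.net.load_state_arrays(best_state)
    return model, history


def predict(model: CNNModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax probabilities for rows of ``x``.

    Evaluation mode (dropout off, batch norm on running stats), so repeated
    calls agree bitwise; argmax breaks ties toward the lower class index.
    """
    logits = model.forward_logits(x, train=False)
    probs = softmax(logits)
    idx = probs.argmax(axis=1)
    if model.classes:
        labels = np.array([model.classes[i] for i in idx], dtype=object)
    else:
        labels = idx
    return labels, probs


def save_model(model: CNNModel, path: str) -> None:
    """Portable checkpoint: npz arrays plus a JSON config header."""
    arrays = {f"arr_{i}": a for i, a in enumerate(model.net.state_arrays())}
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    header = {"cfg": asdict(model.cfg), "classes": model.classes}
    json_path = (path[:-4] if path.endswith(".npz") else path) + ".json"
    with open(json_path, "w") as fh:
        json.dump(header, fh, indent=2, sort_keys=True)


def load_model(path: str) -> CNNModel:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        header = json.load(fh)
    cfg = CNNConfig(**header["cfg"])
    model = build_model(cfg, seed=0)
    model.classes = list(header["classes"])
    with np.load(base + ".npz") as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    model.net.load_state_arrays(arrays)
    return model
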