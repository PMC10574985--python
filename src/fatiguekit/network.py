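"""The seven-block 1-D CNN with interval type-2 fuzzy activations.

The architecture is a fixed stack: an input dropout layer, then seven
convolution blocks (conv -> activation -> max-pool -> batch-norm, with one
extra dropout after the first block), then a dense softmax head.  The first
convolution uses a long kernel (128 samples, stride 20) acting as a learned
filter bank over the raw waveform; the remaining six use kernel 3, stride 1.
Filter counts are 16, 32, then 64 for the five deeper blocks.

With T2F activations each block contributes exactly 3 learnable activation
parameters per output channel (slope, footprint-of-uncertainty width, and
upper/lower membership blend), i.e. 3 x (16 + 32 + 5 x 64) = 1104 in total.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.utils.validation import check_is_fitted

from .io import EpochDataset
from .nn import (BatchNorm1D, Conv1D, Dense, Dropout, Flatten, LeakyReLU,
                 MaxPool1D, ReLU, Sequential, T2FActivation, make_optimizer,
                 softmax, softmax_cross_entropy, t2f)
from .nn.layers import conv_output_length, pool_output_length

ACTIVATIONS = ("t2f", "relu", "leaky_relu")


class TrainingError(RuntimeError):
    """Raised when optimization diverges (NaN/inf loss)."""


@dataclass(frozen=True)
class T2FParams:
    """The three per-channel T2F parameters with their valid ranges."""

    a: float = 1.0        # slope, > 0
    delta: float = 0.0    # footprint-of-uncertainty width, in [0, 1)
    alpha: float = 0.5    # upper/lower membership blend, in [0, 1]

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("slope a must be positive")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must be in [0, 1)")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


def t2f_activation(x: np.ndarray, params: T2FParams) -> np.ndarray:
    """Elementwise T2F unit ``x * [alpha*sig(a(1+d)x) + (1-alpha)*sig(a(1-d)x)]``."""
    return t2f(np.asarray(x, dtype=float), params.a, params.delta, params.alpha)


@dataclass(frozen=True)
class ArchSpec:
    """Declarative encoding of the seven-block convolutional architecture."""

    filters: tuple[int, ...] = (16, 32, 64, 64, 64, 64, 64)
    kernels: tuple[int, ...] = (128, 3, 3, 3, 3, 3, 3)
    strides: tuple[int, ...] = (20, 1, 1, 1, 1, 1, 1)
    pool: int = 2
    dropout_input: float = 0.3
    dropout_after_first: float = 0.3

    def __post_init__(self):
        n = len(self.filters)
        if not (len(self.kernels) == len(self.strides) == n):
            raise ValueError("filters/kernels/strides must have equal length")

    @property
    def n_blocks(self) -> int:
        return len(self.filters)

    def length_chain(self, input_len: int) -> list[int]:
        """Temporal lengths after each conv and pool layer, in order."""
        chain = []
        length = input_len
        for kernel, stride in zip(self.kernels, self.strides):
            length = layer_length(length, ("conv", kernel, stride))
            chain.append(length)
            length = layer_length(length, ("pool", self.pool, self.pool))
            chain.append(length)
        return chain


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults are the tuned optima."""

    optimizer: str = "adadelta"
    loss: str = "cross_entropy"
    batch_size: int = 10
    learning_rate: float = 0.001
    dropout: float = 0.3
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0


def layer_length(input_len: int, layer) -> int:
    """Output temporal length of one conv or pool layer.

    ``layer`` is ("conv", kernel, stride) or ("pool", size, stride).
    Same-padded convolution gives ceil(input_len / stride); non-padded
    pooling gives floor(input_len / pool_stride).
    """
    if input_len < 1:
        raise ValueError(f"input length must be >= 1, got {input_len}")
    kind, _size, stride = layer
    if kind == "conv":
        return conv_output_length(input_len, stride)
    if kind == "pool":
        return pool_output_length(input_len, stride)
    raise ValueError(f"unknown layer kind {kind!r}")


def _make_activation(name: str, channels: int):
    if name == "t2f":
        return T2FActivation(channels)
    if name == "relu":
        return ReLU()
    if name == "leaky_relu":
        return LeakyReLU(0.2)
    raise ValueError(f"activation must be one of {ACTIVATIONS}, got {name!r}")


def build_cnn(arch: ArchSpec, n_classes: int, activation: str = "t2f",
              input_len: int = 15000, in_channels: int = 1,
              seed: int = 0) -> Sequential:
    """Assemble the CNN as a layer stack (softmax applied by the loss head)."""
    if n_classes not in (2, 3, 5):
        raise ValueError(f"n_classes must be 2, 3 or 5, got {n_classes}")
    if activation not in ACTIVATIONS:
        raise ValueError(f"activation must be one of {ACTIVATIONS}")
    rng = np.random.default_rng(seed)
    layers: list = [Dropout(arch.dropout_input)]
    c_in = in_channels
    length = input_len
    for b in range(arch.n_blocks):
        layers.append(Conv1D(c_in, arch.filters[b], arch.kernels[b],
                             arch.strides[b], rng=rng))
        layers.append(_make_activation(activation, arch.filters[b]))
        layers.append(MaxPool1D(arch.pool))
        layers.append(BatchNorm1D(arch.filters[b]))
        if b == 0 and arch.dropout_after_first > 0:
            layers.append(Dropout(arch.dropout_after_first))
        length = pool_output_length(
            conv_output_length(length, arch.strides[b]), arch.pool)
        if length < 1:
            raise ValueError(
                f"input_len={input_len} collapses to zero length at block {b + 1}")
        c_in = arch.filters[b]
    layers.append(Flatten())
    layers.append(Dense(length * c_in, n_classes, rng=rng))
    model = Sequential(layers)
    model.seed_dropout(seed)
    return model


def model_length_chain(model: Sequential, input_len: int,
                       in_channels: int = 1) -> list[int]:
    """Measured temporal length after each conv/pool layer of a built model."""
    x = np.zeros((1, in_channels, input_len))
    chain = []
    for layer in model.layers:
        x = layer.forward(x, training=False)
        if isinstance(layer, (Conv1D, MaxPool1D)):
            chain.append(x.shape[-1])
        if isinstance(layer, Flatten):
            break
    return chain


def activation_param_count(model: Sequential) -> int:
    """Total learnable activation parameters (3C per T2F layer, else 0)."""
    return sum(p.value.size for layer in model.layers
               if isinstance(layer, T2FActivation) for p in layer.params())


def split_dataset(dataset, fractions=(0.70, 0.10, 0.20), seed: int = 0,
                  stratified: bool = True):
    """Partition into train/validation/test (default 70/10/20).

    Accepts an EpochDataset (returns EpochDataset subsets) or an (X, y)
    pair (returns index-based subsets of both).  The partition is disjoint
    and exhaustive; with ``stratified`` each class is split by the same
    fractions.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    if isinstance(dataset, EpochDataset):
        labels = dataset.labels
        n = len(dataset)
    else:
        X, y = dataset
        labels = np.asarray(y)
        n = len(labels)

    rng = np.random.default_rng(seed)
    groups = ([labels == c for c in np.unique(labels)] if stratified
              else [np.ones(n, dtype=bool)])
    idx_train, idx_val, idx_test = [], [], []
    for mask in groups:
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        m = len(idx)
        b1 = int(round(fractions[0] * m))
        b2 = int(round((fractions[0] + fractions[1]) * m))
        idx_train.append(idx[:b1])
        idx_val.append(idx[b1:b2])
        idx_test.append(idx[b2:])
    parts = [np.sort(np.concatenate(p)) for p in (idx_train, idx_val, idx_test)]
    if isinstance(dataset, EpochDataset):
        return tuple(dataset.subset(p) for p in parts)
    return tuple((X[p], labels[p]) for p in parts)


def _as_xy(data):
    if isinstance(data, EpochDataset):
        return data.epochs, data.labels
    return data


class FatigueCNN(BaseEstimator, ClassifierMixin):
    """Scikit-learn classifier wrapping the seven-block CNN.

    Parameters
    ----------
    arch : ArchSpec or None
        Layer schedule; None means the standard seven-block architecture.
    activation : {"t2f", "relu", "leaky_relu"}
    optimizer : {"adadelta", "rmsprop", "adam", "adamax", "sgd"}
    channel_mode : {"concat", "multichannel"}
        How (n, channels, samples) input enters the network: concatenated
        into one long vector (default) or as separate input channels.
    max_epochs, patience, validation_fraction
        Early stopping monitors validation accuracy when a validation set
        is available (explicit or held out via ``validation_fraction``).

    Attributes
    ----------
    classes_ : original class labels.
    model_ : the fitted layer stack.
    history_ : dict of per-epoch train/validation loss and accuracy.
    """

    def __init__(self, arch: ArchSpec | None = None, activation: str = "t2f",
                 optimizer: str = "adadelta", learning_rate: float = 0.001,
                 batch_size: int = 10, max_epochs: int = 50,
                 patience: int = 10, validation_fraction: float = 0.0,
                 channel_mode: str = "concat", center_input: bool = True,
                 lr_decay: float = 1.0, lr_step: int = 10,
                 weight_decay: float = 0.0, seed: int = 0):
        self.arch = arch
        self.activation = activation
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.channel_mode = channel_mode
        self.center_input = center_input
        self.lr_decay = lr_decay
        self.lr_step = lr_step
        self.weight_decay = weight_decay
        self.seed = seed

    # -- input shaping -----------------------------------------------------
    def _shape_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[:, None, :]
        elif X.ndim == 3:
            if self.channel_mode == "concat":
                X = X.reshape(len(X), 1, -1)
            elif self.channel_mode != "multichannel":
                raise ValueError("channel_mode must be 'concat' or 'multichannel'")
        else:
            raise ValueError("X must be (n, samples) or (n, channels, samples)")
        if self.center_input:
            # [0,1]-normalized epochs are mapped to [-1,1] so that the input
            # dropout layer injects zero-mean rather than offset noise
            X = (X - 0.5) * 2.0
        return X

    def _evaluate(self, X, y):
        logits = self._predict_logits(X)
        loss, _, proba = softmax_cross_entropy(logits, y)
        acc = float((proba.argmax(axis=1) == y).mean())
        return float(loss), acc

    def _predict_logits(self, X, batch: int = 64):
        out = [self.model_.forward(X[i: i + batch], training=False)
               for i in range(0, len(X), batch)]
        return np.concatenate(out)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, validation_data=None):
        X, y = _as_xy((X, y)) if not isinstance(X, EpochDataset) else (X.epochs, X.labels)
        X = self._shape_input(X)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        arch = self.arch or ArchSpec()
        rng = np.random.default_rng(self.seed)

        if validation_data is not None:
            Xv, yv = _as_xy(validation_data)
            Xv = self._shape_input(np.asarray(Xv))
            yv = np.searchsorted(self.classes_, np.asarray(yv))
            Xt, yt = X, y_enc
        elif self.validation_fraction > 0:
            f = self.validation_fraction
            (Xt, yt), (Xv, yv), _ = split_dataset(
                (X, y_enc), (1 - f - 1e-12, f, 1e-12), seed=self.seed)
            if len(Xv) == 0:
                Xv = yv = None
        else:
            Xt, yt, Xv, yv = X, y_enc, None, None

        self.model_ = build_cnn(arch, n_classes, self.activation,
                                input_len=X.shape[2], in_channels=X.shape[1],
                                seed=self.seed)
        params = self.model_.params()
        bn_layers = [l for l in self.model_.layers if isinstance(l, BatchNorm1D)]

        def _snapshot():
            return ([p.value.copy() for p in params],
                    [(l.running_mean.copy(), l.running_var.copy())
                     for l in bn_layers])

        def _restore(snap):
            values, stats = snap
            for p, v in zip(params, values):
                p.value[...] = v
            for l, (m, v) in zip(bn_layers, stats):
                l.running_mean, l.running_var = m.copy(), v.copy()

        opt = make_optimizer(self.optimizer, params, self.learning_rate)
        self.history_ = {"loss": [], "accuracy": [],
                         "val_loss": [], "val_accuracy": []}
        best = (-np.inf, np.inf, None)  # (val acc, val loss, snapshot)
        since_best = 0
        n = len(Xt)
        for epoch in range(self.max_epochs):
            if self.lr_decay != 1.0 and epoch > 0 and epoch % self.lr_step == 0:
                opt.lr *= self.lr_decay
            order = rng.permutation(n)
            ep_loss, ep_correct = 0.0, 0
            for i in range(0, n, self.batch_size):
                idx = order[i: i + self.batch_size]
                xb, yb = Xt[idx], yt[idx]
                self.model_.zero_grad()
                logits = self.model_.forward(xb, training=True)
                loss, gy, proba = softmax_cross_entropy(logits, yb)
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"loss diverged at epoch {epoch}, step {i // self.batch_size}: "
                        f"loss={loss}; try a lower learning rate")
                self.model_.backward(gy)
                if self.weight_decay:
                    # L2 penalty on convolution/dense weights only
                    for p in params:
                        if p.name.endswith(".w"):
                            p.grad += self.weight_decay * p.value
                opt.step()
                ep_loss += loss * len(idx)
                ep_correct += int((proba.argmax(axis=1) == yb).sum())
            self.history_["loss"].append(ep_loss / n)
            self.history_["accuracy"].append(ep_correct / n)
            if Xv is not None and len(Xv):
                vl, va = self._evaluate(Xv, yv)
                self.history_["val_loss"].append(vl)
                self.history_["val_accuracy"].append(va)
                # best validation accuracy, ties broken by validation loss
                if va > best[0] or (va == best[0] and vl < best[1]):
                    improved = va > best[0]
                    best = (va, vl, _snapshot())
                    if improved:
                        since_best = 0
                else:
                    since_best += 1
                    if self.patience and since_best >= self.patience:
                        break
        if best[2] is not None:
            _restore(best[2])
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = self._shape_input(np.asarray(X) if not isinstance(X, EpochDataset)
                              else X.epochs)
        return softmax(self._predict_logits(X))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y):
        y = y if not isinstance(X, EpochDataset) else X.labels
        return float((self.predict(X) == np.asarray(y)).mean())


def train_classifier(train, validation, arch: ArchSpec | None = None,
                     train_config: TrainConfig | None = None,
                     activation: str = "t2f", seed: int | None = None,
                     channel_mode: str = "concat"):
    """Fit a FatigueCNN on an explicit train/validation pair.

    Returns the fitted estimator (its best-validation checkpoint restored)
    and the per-epoch history.
    """
    cfg = train_config or TrainConfig()
    clf = FatigueCNN(arch=arch, activation=activation,
                     optimizer=cfg.optimizer, learning_rate=cfg.learning_rate,
                     batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
                     patience=cfg.patience, channel_mode=channel_mode,
                     seed=cfg.seed if seed is None else seed)
    Xt, yt = _as_xy(train if not isinstance(train, EpochDataset)
                    else (train.epochs, train.labels))
    val = None
    if validation is not None:
        val = _as_xy(validation if not isinstance(validation, EpochDataset)
                     else (validation.epochs, validation.labels))
        if len(val[0]) == 0:
            val = None
    clf.fit(Xt, yt, validation_data=val)
    return clf, clf.history_


def kfold_cv(dataset, k: int = 5, arch: ArchSpec | None = None,
             train_config: TrainConfig | None = None,
             activation: str = "t2f", seed: int = 0,
             channel_mode: str = "concat", stratified: bool = True):
    """Five-fold (by default) cross-validation with per-fold metric reports.

    Returns (reports, mean_accuracy, sd_accuracy, fold_test_indices).
    """
    from .evaluate import confusion_and_metrics

    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = _as_xy(dataset if not isinstance(dataset, EpochDataset)
                  else (dataset.epochs, dataset.labels))
    if len(X) < k:
        raise ValueError(f"dataset of size {len(X)} cannot be split into {k} folds")
    cfg = train_config or TrainConfig()
    splitter = (StratifiedKFold(k, shuffle=True, random_state=seed)
                if stratified else KFold(k, shuffle=True, random_state=seed))
    classes = np.unique(y)
    reports, accs, fold_idx = [], [], []
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        clf = FatigueCNN(arch=arch, activation=activation,
                         optimizer=cfg.optimizer,
                         learning_rate=cfg.learning_rate,
                         batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
                         patience=0, channel_mode=channel_mode,
                         seed=seed + fold)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        rep = confusion_and_metrics(y[te], pred, n_classes=len(classes),
                                    labels=classes)
        reports.append(rep)
        accs.append(rep.accuracy)
        fold_idx.append(te)
    return reports, float(np.mean(accs)), float(np.std(accs)), fold_idx


def save_model(clf: FatigueCNN, path) -> None:
    """Persist a fitted classifier to a single portable .npz checkpoint.

    The file embeds the architecture and estimator parameters as JSON next
    to every weight array and batch-norm running statistic.
    """
    check_is_fitted(clf, "model_")
    arch = clf.arch or ArchSpec()
    meta = {
        "arch": asdict(arch),
        "params": {k: v for k, v in clf.get_params().items() if k != "arch"},
        "classes": np.asarray(clf.classes_).tolist(),
        "n_features_in": int(clf.n_features_in_),
    }
    arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, p in enumerate(clf.model_.params()):
        arrays[f"p{i:03d}"] = p.value
    for i, layer in enumerate(clf.model_.layers):
        if isinstance(layer, BatchNorm1D):
            arrays[f"bn{i:03d}_mean"] = layer.running_mean
            arrays[f"bn{i:03d}_var"] = layer.running_var
    np.savez(path, **arrays)


def load_model(path) -> FatigueCNN:
    """Rebuild a fitted classifier from a checkpoint written by save_model."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        arch = ArchSpec(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in meta["arch"].items()})
        clf = FatigueCNN(arch=arch, **meta["params"])
        clf.classes_ = np.asarray(meta["classes"])
        clf.n_features_in_ = meta["n_features_in"]
        n_ch = 1 if clf.channel_mode == "concat" else None
        input_len = meta["n_features_in"]
        if n_ch is None:
            raise ValueError("multichannel checkpoints must record channel count")
        clf.model_ = build_cnn(arch, len(clf.classes_), clf.activation,
                               input_len=input_len, in_channels=1,
                               seed=clf.seed)
        for i, p in enumerate(clf.model_.params()):
            p.value[...] = data[f"p{i:03d}"]
        for i, layer in enumerate(clf.model_.layers):
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = data[f"bn{i:03d}_mean"]
                layer.running_var = data[f"bn{i:03d}_var"]
        clf.history_ = {}
    return clf
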