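"""CNN classifier construction, warm-up training protocol and last-conv
feature extraction.

The architecture is three convolutional blocks (conv / ReLU / max-pool /
dropout) and an output block (dense / ReLU / dropout / dense) ending in a
sigmoid unit for the binary tasks or a 3-way softmax for the three-class
task. The last convolutional block carries 500 filters so the pooled
activations double as a 500-dimensional sequence feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Conv1D, ConvNet, Dense, Dropout, Flatten, MaxPool1D, ReLU

__all__ = ["BlockSpec", "CnnSpec", "build_cnn", "train_cnn",
           "extract_cnn_features", "TrainingLog", "N_CNN_FEATURES"]

N_CNN_FEATURES = 500

DEFAULT_LR_GRID = (0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class BlockSpec:
    filters: int
    kernel: int
    pool: int
    dropout: float


@dataclass(frozen=True)
class CnnSpec:
    blocks: tuple[BlockSpec, ...] = (
        BlockSpec(128, 15, 4, 0.2),
        BlockSpec(256, 5, 4, 0.2),
        BlockSpec(500, 3, 4, 0.2),
    )
    hidden_units: int = 64
    head_dropout: float = 0.5

    def __post_init__(self) -> None:
        if len(self.blocks) < 1:
            raise ValueError("need at least one convolutional block")

    @classmethod
    def small(cls, last_filters: int = 32) -> "CnnSpec":
        """A reduced architecture for CPU-bound experiments and tests."""
        return cls(
            blocks=(
                BlockSpec(16, 15, 4, 0.1),
                BlockSpec(32, 5, 4, 0.1),
                BlockSpec(last_filters, 3, 4, 0.1),
            ),
            hidden_units=32,
            head_dropout=0.2,
        )

    def min_input_len(self) -> int:
        need = 1
        for block in reversed(self.blocks):
            need = need * block.pool + block.kernel - 1
        return need

    def conv_output_len(self, input_len: int) -> int:
        length = input_len
        for block in self.blocks:
            length = (length - block.kernel + 1) // block.pool
        return length


def build_cnn(spec: CnnSpec, in_channels: int, input_len: int,
              n_classes: int = 2) -> ConvNet:
    """Build an untrained network for L x C inputs.

    ``n_classes=2`` yields a single sigmoid output unit; ``n_classes=3`` a
    3-way softmax head.
    """
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    if input_len < spec.min_input_len():
        raise ValueError(
            f"input length {input_len} too short for the pooling cascade; "
            f"minimum is {spec.min_input_len()}"
        )
    layers: list = []
    channels = in_channels
    last_conv_index = None
    for block in spec.blocks:
        layers.append(Conv1D(channels, block.filters, block.kernel))
        layers.append(ReLU())
        last_conv_index = len(layers) - 1
        layers.append(MaxPool1D(block.pool))
        layers.append(Dropout(block.dropout))
        channels = block.filters
    flat = channels * spec.conv_output_len(input_len)
    n_outputs = 1 if n_classes == 2 else 3
    layers += [
        Flatten(),
        Dense(flat, spec.hidden_units),
        ReLU(),
        Dropout(spec.head_dropout),
        Dense(spec.hidden_units, n_outputs),
    ]
    model = ConvNet(layers, n_outputs, last_conv_index=last_conv_index)
    model.spec = spec
    model.in_channels = in_channels
    model.input_len = input_len
    model.initialize(0)
    return model


def _as_batch(X: np.ndarray) -> np.ndarray:
    """Accept (N, L, C) encoded batches and convert to (N, C, L)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a batch of L x C encodings")
    return np.transpose(X, (0, 2, 1))


@dataclass
class TrainingLog:
    chosen_lr: float = 0.0
    chosen_init_seed: int = 0
    warmup_losses: dict = field(default_factory=dict)
    epoch_val_losses: list = field(default_factory=list)
    best_val_loss: float = np.inf
    best_epoch: int = -1


def train_cnn(
    model: ConvNet,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    lr_grid: tuple[float, ...] = DEFAULT_LR_GRID,
    batch_size: int = 300,
    seed: int = 0,
    warmup_inits: int = 3,
    warmup_epochs: int = 5,
    max_epochs: int = 100,
    patience: int = 10,
) -> tuple[ConvNet, TrainingLog]:
    """Warm-up then full training with Adam and cross-entropy.

    The warm-up phase trains briefly for every (random initialization,
    learning rate) pair, keeps the pair with the lowest validation loss, then
    re-trains from that stored initialization with early stopping on
    validation loss. Fully deterministic given ``seed``.
    """
    X_train, y_train = train_set
    X_val, y_val = val_set
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    Xtr = _as_batch(X_train)
    Xva = _as_batch(X_val)
    ytr = np.asarray(y_train)
    yva = np.asarray(y_val)

    log = TrainingLog()
    best = (np.inf, None, None)  # (val loss, init seed, lr)
    for init_idx in range(warmup_inits):
        init_seed = seed * 1000 + init_idx
        for lr in lr_grid:
            model.initialize(init_seed)
            _fit(model, Xtr, ytr, lr, batch_size, warmup_epochs,
                 rng_seed=(seed, init_idx, int(lr * 1e6)))
            val_loss = model.loss(Xva, yva)
            log.warmup_losses[(init_seed, lr)] = val_loss
            if val_loss < best[0]:
                best = (val_loss, init_seed, lr)

    _, init_seed, lr = best
    log.chosen_init_seed = init_seed
    log.chosen_lr = lr
    model.initialize(init_seed)
    optimizer = Adam(model.params(), lr=lr)
    rng = np.random.default_rng([seed, 7919])
    best_weights = model.get_weights()
    bad_epochs = 0
    for epoch in range(max_epochs):
        _run_epoch(model, Xtr, ytr, optimizer, batch_size, rng)
        val_loss = model.loss(Xva, yva)
        log.epoch_val_losses.append(val_loss)
        if val_loss < log.best_val_loss - 1e-6:
            log.best_val_loss = val_loss
            log.best_epoch = epoch
            best_weights = model.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    model.set_weights(best_weights)
    return model, log


def _fit(model, X, y, lr, batch_size, epochs, rng_seed):
    optimizer = Adam(model.params(), lr=lr)
    rng = np.random.default_rng(list(rng_seed))
    for _ in range(epochs):
        _run_epoch(model, X, y, optimizer, batch_size, rng)


def _run_epoch(model, X, y, optimizer, batch_size, rng):
    order = rng.permutation(len(X))
    for start in range(0, len(X), batch_size):
        idx = order[start : start + batch_size]
        model.train_step(X[idx], y[idx], optimizer, rng)


def extract_cnn_features(model: ConvNet, encoded: np.ndarray) -> np.ndarray:
    """Global max over positions of each last-conv-layer filter activation.

    ``encoded`` is one L x C example or an (N, L, C) batch; returns 500
    features per example (the last block's filter count).
    """
    spec: CnnSpec = getattr(model, "spec", None)
    if spec is None or model.last_conv_index is None:
        raise ValueError("model was not built with build_cnn")
    if spec.blocks[-1].filters != N_CNN_FEATURES:
        raise ValueError(
            f"feature extraction requires a {N_CNN_FEATURES}-filter last "
            f"block, got {spec.blocks[-1].filters}"
        )
    single = encoded.ndim == 2
    batch = _as_batch(encoded[None] if single else encoded)
    acts = batch
    for layer in model.layers[: model.last_conv_index + 1]:
        acts = layer.forward(acts, train=False)
    features = acts.max(axis=2)
    return features[0] if single else features
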