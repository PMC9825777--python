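"""Minimal deterministic 1-D convolutional network on NumPy.

Implements exactly the layer vocabulary the classifier architecture needs
(conv / ReLU / max-pool / dropout / dense) with Adam and cross-entropy
training. Keeping the network in NumPy makes every run bit-reproducible from
an explicit seed and gives the attribution code direct access to layer
activations.

Internally activations are (N, C, L) batches; the public encoders produce
L x C matrices which the model transposes on entry.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "ConvNet",
    "Adam",
]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def initialize(self, rng: np.random.Generator) -> None:
        pass

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding 1-D convolution over (N, C, L) inputs."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.W = np.zeros((out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def initialize(self, rng: np.random.Generator) -> None:
        fan_in = self.in_channels * self.kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.W.shape)
        self.b = np.zeros(self.out_channels)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        if x.shape[2] < self.kernel:
            raise ValueError(
                f"input length {x.shape[2]} shorter than kernel {self.kernel}"
            )
        if train:
            self._x = x
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        return np.einsum("nclk,ock->nol", windows, self.W, optimize=True) + \
            self.b[None, :, None]

    def backward(self, grad):
        x = self._x
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        self.dW[...] = np.einsum("nol,nclk->ock", grad, windows, optimize=True)
        self.db[...] = grad.sum(axis=(0, 2))
        k = self.kernel
        padded = np.pad(grad, ((0, 0), (0, 0), (k - 1, k - 1)))
        gwin = np.lib.stride_tricks.sliding_window_view(padded, k, axis=2)
        return np.einsum("nopj,ocj->ncp", gwin, self.W[:, :, ::-1], optimize=True)


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the
    pool width is dropped."""

    def __init__(self, width: int):
        self.width = width
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x, train=False, rng=None):
        p = self.width
        n_out = x.shape[2] // p
        if n_out < 1:
            raise ValueError(
                f"input length {x.shape[2]} shorter than pool width {p}"
            )
        trimmed = x[:, :, : n_out * p].reshape(x.shape[0], x.shape[1], n_out, p)
        if train:
            self._argmax = trimmed.argmax(axis=3)
            self._in_shape = x.shape
        return trimmed.max(axis=3)

    def backward(self, grad):
        n, c, n_out = grad.shape
        p = self.width
        out = np.zeros(self._in_shape)
        view = out[:, :, : n_out * p].reshape(n, c, n_out, p)
        idx = np.indices((n, c, n_out))
        view[idx[0], idx[1], idx[2], self._argmax] = grad
        return out


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape: tuple | None = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int):
        self.in_features = in_features
        self.out_features = out_features
        self.W = np.zeros((out_features, in_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def initialize(self, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / self.in_features), self.W.shape)
        self.b = np.zeros(self.out_features)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """A sequential conv network with a sigmoid (1 unit) or softmax (k units)
    head. ``layers`` ends with the output Dense; probabilities are produced
    on demand."""

    def __init__(self, layers: list[Layer], n_outputs: int,
                 last_conv_index: int | None = None):
        self.layers = layers
        self.n_outputs = n_outputs
        self.last_conv_index = last_conv_index  # index of last conv block's ReLU

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.initialize(rng)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def forward_trace(self, x: np.ndarray) -> list[np.ndarray]:
        """Evaluation-mode activations: acts[0] is the input, acts[i+1] the
        output of layer i (used by attribution and feature extraction)."""
        acts = [x]
        for layer in self.layers:
            x = layer.forward(x, train=False)
            acts.append(x)
        return acts

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward_logits(x)
        if self.n_outputs == 1:
            p = 1.0 / (1.0 + np.exp(-logits[:, 0]))
            return p
        return _softmax(logits)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        return self._loss_from_logits(self.forward_logits(x), y)

    def _loss_from_logits(self, logits: np.ndarray, y: np.ndarray) -> float:
        if self.n_outputs == 1:
            z = logits[:, 0]
            # log(1 + exp(z)) - y z, numerically stable
            return float(np.mean(np.logaddexp(0.0, z) - y * z))
        probs = _softmax(logits)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: Adam,
                   rng: np.random.Generator) -> float:
        logits = self.forward_logits(x, train=True, rng=rng)
        n = x.shape[0]
        if self.n_outputs == 1:
            p = 1.0 / (1.0 + np.exp(-logits[:, 0]))
            dlogits = ((p - y) / n)[:, None]
        else:
            probs = _softmax(logits)
            probs[np.arange(n), y] -= 1.0
            dlogits = probs / n
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        optimizer.step(self.grads())
        return self._loss_from_logits(logits, y)
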