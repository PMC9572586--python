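"""A small numpy neural-network engine.

Implements exactly the layer types the classifier branches need — dense,
1-D/2-D convolution (stride 1, odd kernel, 'same' padding), max pooling,
ReLU, dropout, flatten — with hand-written backpropagation and an SGD
optimizer with classical momentum.  Convolutions are evaluated as batched
im2col matrix products; the input gradient of a stride-1 same-padded
convolution is itself a convolution with the channel-transposed,
spatially-flipped kernel, which keeps the backward pass in BLAS as well.

All parameters and activations are float32.  Every source of randomness
(weight init, dropout masks) is drawn from generators spawned from a single
seed, so building and training a network twice with the same seed is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv1D",
    "Conv2D",
    "MaxPool1D",
    "MaxPool2D",
    "ReLU",
    "Dropout",
    "Flatten",
    "Sequential",
    "SGD",
    "softmax_logits",
    "softmax_cross_entropy",
]


def softmax_logits(z: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax of a (batch, classes) logit matrix."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of integer labels under softmax(logits).

    Returns ``(loss, probs, dlogits)`` where ``dlogits`` is the gradient of
    the mean loss with respect to the logits.
    """
    probs = softmax_logits(logits)
    n = logits.shape[0]
    p_true = np.clip(probs[np.arange(n), labels], 1e-12, 1.0)
    loss = float(-np.log(p_true).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, probs, dlogits


class Layer:
    """Base class; stateless layers override forward/backward only."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, init: str = "he"):
        super().__init__()
        scale = np.sqrt(2.0 / n_in) if init == "he" else np.sqrt(1.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32),
            "b": np.zeros(n_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"][...] = self._x.T @ g
        self.grads["b"][...] = g.sum(axis=0)
        return g @ self.params["W"].T


def _im2col1d(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L+k-1 padded) -> (B, L, C*k) patch matrix."""
    sw = sliding_window_view(x, k, axis=2)  # (B, C, L, k)
    b, c, l, _ = sw.shape
    return np.ascontiguousarray(sw.transpose(0, 2, 1, 3)).reshape(b, l, c * k)


class Conv1D(Layer):
    """Stride-1, same-padded 1-D convolution over (B, C, L) inputs."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("Conv1D supports odd kernel sizes only")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_in * kernel, c_out)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        self._cols = _im2col1d(xp, self.k)  # (B, L, C*k)
        y = self._cols @ self.params["W"] + self.params["b"]  # (B, L, O)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 1))  # (B, L, O)
        b, l, o = gl.shape
        self.grads["W"][...] = np.tensordot(self._cols, gl, axes=([0, 1], [0, 1]))
        self.grads["b"][...] = gl.sum(axis=(0, 1))
        # dX = conv(g, W^T flipped): build the transposed kernel (O*k, C)
        W = self.params["W"].reshape(self.c_in, self.k, self.c_out)
        V = W[:, ::-1, :].transpose(2, 1, 0).reshape(self.c_out * self.k, self.c_in)
        pad = self.k // 2
        gp = np.pad(gl.transpose(0, 2, 1), ((0, 0), (0, 0), (pad, pad)))
        return (_im2col1d(gp, self.k) @ V).transpose(0, 2, 1)


def _im2col2d(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H+2p, W+2p) -> (B, H*W, C*k*k) patch matrix."""
    sw = sliding_window_view(x, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    b, c, h, w, _, _ = sw.shape
    return np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * k * k)


class Conv2D(Layer):
    """Stride-1, same-padded 2-D convolution over (B, C, H, W) inputs."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("Conv2D supports odd kernel sizes only")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_in * kernel * kernel, c_out)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        self._hw = x.shape[2], x.shape[3]
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        self._cols = _im2col2d(xp, self.k)  # (B, H*W, C*k*k)
        y = self._cols @ self.params["W"] + self.params["b"]  # (B, H*W, O)
        h, w = self._hw
        return np.ascontiguousarray(y.transpose(0, 2, 1)).reshape(x.shape[0], self.c_out, h, w)

    def backward(self, g):
        b = g.shape[0]
        h, w = self._hw
        gl = np.ascontiguousarray(g.reshape(b, self.c_out, h * w).transpose(0, 2, 1))
        self.grads["W"][...] = np.tensordot(self._cols, gl, axes=([0, 1], [0, 1]))
        self.grads["b"][...] = gl.sum(axis=(0, 1))
        W = self.params["W"].reshape(self.c_in, self.k, self.k, self.c_out)
        V = W[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.c_out * self.k * self.k, self.c_in)
        pad = self.k // 2
        gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        dx = _im2col2d(gp, self.k) @ V  # (B, H*W, C_in)
        return np.ascontiguousarray(dx.transpose(0, 2, 1)).reshape(b, self.c_in, h, w)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        b, c, l = x.shape
        lo = l // self.size
        self._in_len = l
        win = x[:, :, : lo * self.size].reshape(b, c, lo, self.size)
        self._idx = win.argmax(axis=3)
        return win.max(axis=3)

    def backward(self, g):
        b, c, lo = g.shape
        out = np.zeros((b, c, self._in_len), dtype=g.dtype)
        win = out[:, :, : lo * self.size].reshape(b, c, lo, self.size)
        np.put_along_axis(win, self._idx[..., None], g[..., None], axis=3)
        return out


class MaxPool2D(Layer):
    """Non-overlapping 2-D max pooling; remainder rows/cols are dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        b, c, h, w = x.shape
        s = self.size
        ho, wo = h // s, w // s
        self._in_shape = (h, w)
        win = (
            x[:, :, : ho * s, : wo * s]
            .reshape(b, c, ho, s, wo, s)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, ho, wo, s * s)
        )
        self._idx = win.argmax(axis=4)
        return win.max(axis=4)

    def backward(self, g):
        b, c, ho, wo = g.shape
        s = self.size
        h, w = self._in_shape
        win = np.zeros((b, c, ho, wo, s * s), dtype=g.dtype)
        np.put_along_axis(win, self._idx[..., None], g[..., None], axis=4)
        out = np.zeros((b, c, h, w), dtype=g.dtype)
        out[:, :, : ho * s, : wo * s] = (
            win.reshape(b, c, ho, wo, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho * s, wo * s)
        )
        return out


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        self.last_width = int(np.prod(x.shape[1:]))
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential:
    """A feed-forward stack ending in class logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [
            softmax_logits(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer.params[name], layer.grads[name]

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                out[f"layer{i}.{name}"] = value
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i}.{name}"]


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, net: Sequential, lr: float, momentum: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p) for p, _ in net.parameters()]

    def step(self) -> None:
        for v, (p, g) in zip(self._velocity, self.net.parameters()):
            v *= self.momentum
            v -= self.lr * g
            p += v
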