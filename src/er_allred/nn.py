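"""Minimal convolutional-network layer stack trained with stochastic gradient descent.

Provides exactly the ingredients the detection and stain-intensity models need:
stride-1 "same" 3x3/5x5 convolutions (im2col), ReLU, 2x2 max-pooling, nearest
2x upsampling, dropout, and a dense softmax/regression head. Arrays use NHWC
layout in float32. All randomness (weight init, dropout masks) flows from a
single numpy Generator so training is reproducible for a fixed seed on a
single thread.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Dropout",
    "Flatten",
    "Dense",
    "Network",
    "SGD",
    "mse_loss",
    "softmax",
    "softmax_xent_loss",
    "layers_from_config",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding k x k windows of a zero-padded NHWC batch, as a 2-D matrix.

    Returns shape (N*H*W, k*k*C); rows are row-major over (n, i, j).
    """
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win).reshape(n * h * w, k * k * c)


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def config(self) -> dict:
        raise NotImplementedError

    # receptive-field bookkeeping: (size, stride) growth contributed by the layer
    def rf(self, size: int, stride: int) -> tuple[int, int]:
        return size, stride


class Conv2D(Layer):
    """Stride-1 same-padding convolution; odd kernel size only."""

    trainable = True

    def __init__(self, cin: int, cout: int, k: int = 3):
        if k % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {k}")
        self.cin, self.cout, self.k = cin, cout, k
        self.w = np.zeros((k * k * cin, cout), dtype=np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def init_params(self, rng: np.random.Generator) -> None:
        # zero-mean Gaussian, He-scaled by fan-in
        std = np.sqrt(2.0 / (self.k * self.k * self.cin))
        self.w = (rng.standard_normal(self.w.shape) * std).astype(np.float32)
        self.b = np.zeros(self.cout, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols if train else None
        y = cols @ self.w + self.b
        return y.reshape(x.shape[0], x.shape[1], x.shape[2], self.cout)

    def backward(self, dy):
        n, h, w, _ = self._shape
        dy_flat = dy.reshape(n * h * w, self.cout)
        self.dw = self._cols.T @ dy_flat
        self.db = dy_flat.sum(axis=0)
        # grad wrt input: correlate dy with spatially flipped, channel-swapped kernel
        wk = self.w.reshape(self.k, self.k, self.cin, self.cout)
        wk_t = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(self.k * self.k * self.cout,
                                                            self.cin)
        dx = _im2col(dy, self.k) @ np.ascontiguousarray(wk_t)
        return dx.reshape(self._shape)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def set_params(self, arrays: Sequence[np.ndarray]) -> None:
        self.w, self.b = [a.astype(np.float32) for a in arrays]

    def config(self):
        return {"type": "conv", "cin": self.cin, "cout": self.cout, "k": self.k}

    def rf(self, size, stride):
        return size + (self.k - 1) * stride, stride


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)

    def config(self):
        return {"type": "relu"}


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input height/width must be even."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._shape
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        xr = flat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return xr.reshape(n, h, w, c)

    def config(self):
        return {"type": "maxpool"}

    def rf(self, size, stride):
        return size + stride, stride * 2


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=False, rng=None):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))

    def config(self):
        return {"type": "upsample"}

    def rf(self, size, stride):
        return size, max(stride // 2, 1)


class Dropout(Layer):
    def __init__(self, p: float = 0.5):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        return dy if self._mask is None else (dy * self._mask).astype(np.float32)

    def config(self):
        return {"type": "dropout", "p": self.p}


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def config(self):
        return {"type": "flatten"}


class Dense(Layer):
    trainable = True

    def __init__(self, nin: int, nout: int):
        self.nin, self.nout = nin, nout
        self.w = np.zeros((nin, nout), dtype=np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def init_params(self, rng: np.random.Generator) -> None:
        std = np.sqrt(2.0 / self.nin)
        self.w = (rng.standard_normal(self.w.shape) * std).astype(np.float32)
        self.b = np.zeros(self.nout, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def set_params(self, arrays: Sequence[np.ndarray]) -> None:
        self.w, self.b = [a.astype(np.float32) for a in arrays]

    def config(self):
        return {"type": "dense", "nin": self.nin, "nout": self.nout}


def layers_from_config(cfg: Sequence[dict]) -> list[Layer]:
    out: list[Layer] = []
    for c in cfg:
        t = c["type"]
        if t == "conv":
            out.append(Conv2D(c["cin"], c["cout"], c["k"]))
        elif t == "relu":
            out.append(ReLU())
        elif t == "maxpool":
            out.append(MaxPool2())
        elif t == "upsample":
            out.append(Upsample2())
        elif t == "dropout":
            out.append(Dropout(c["p"]))
        elif t == "flatten":
            out.append(Flatten())
        elif t == "dense":
            out.append(Dense(c["nin"], c["nout"]))
        else:
            raise ValueError(f"unknown layer type {t!r}")
    return out


class Network:
    """An ordered layer stack with save/load to a self-describing npz archive."""

    def __init__(self, layers: Sequence[Layer], meta: dict | None = None):
        self.layers = list(layers)
        self.meta = dict(meta or {})

    def init_params(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if layer.trainable:
                layer.init_params(rng)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = []
        for layer in self.layers:
            if layer.trainable:
                out.extend(layer.params())
        return out

    def receptive_field(self) -> int:
        size, stride = 1, 1
        for layer in self.layers:
            size, stride = layer.rf(size, stride)
        return size

    def save(self, path) -> None:
        arrays: dict[str, np.ndarray] = {}
        i = 0
        for layer in self.layers:
            if layer.trainable:
                for a, _ in layer.params():
                    arrays[f"p{i}"] = a
                    i += 1
        header = json.dumps({"layers": [l.config() for l in self.layers],
                             "meta": self.meta})
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            net = cls(layers_from_config(header["layers"]), meta=header["meta"])
            i = 0
            for layer in net.layers:
                if layer.trainable:
                    n = len(layer.params())
                    layer.set_params([z[f"p{j}"] for j in range(i, i + n)])
                    i += n
        return net


class SGD:
    """Plain stochastic gradient descent with optional momentum."""

    def __init__(self, net: Network, lr: float, momentum: float = 0.0):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p) for p, _ in net.params()]

    def step(self) -> None:
        for v, (p, g) in zip(self._vel, self.net.params()):
            if self.momentum:
                v *= self.momentum
                v -= self.lr * g
                p += v
            else:
                p -= self.lr * g


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient wrt pred."""
    diff = (pred - target).astype(np.float32)
    return float(np.mean(diff ** 2)), (2.0 / diff.size) * diff


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent_loss(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy over integer labels; returns (loss, grad wrt logits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
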