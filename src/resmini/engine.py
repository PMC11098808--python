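"""Minimal NumPy neural-network engine backing the trainable ResMini model.

Implements exactly the layers the ResMini plan needs — 2D convolution
(im2col/col2im), batch normalization with running statistics, ReLU, 3x3
max pooling, global average pooling, a dense layer and a softmax
cross-entropy head — each with an explicit ``forward``/``backward`` pair,
plus the Adam optimizer.  Everything is float32 and deterministic given a
seeded ``numpy.random.Generator``.

Tensors follow the (N, C, H, W) layout.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int,
            pad_value: float = 0.0):
    """Unfold (N,C,H,W) into (N*Ho*Wo, C*kh*kw) patch rows."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=pad_value)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(col), ho, wo


def _col2im(dcol: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    d = dcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += d[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Layer:
    """Base class: parameters live in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        # non-trainable state (e.g. BN running statistics)
        self.state: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = stride, pad
        fan_in = cin * k * k
        # He-normal initialization, standard for ReLU networks
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)).astype(DTYPE)

    def forward(self, x, training):
        self._x_shape = x.shape
        col, ho, wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._col, self._ho, self._wo = col, ho, wo
        out = col @ self.params["W"].reshape(self.cout, -1).T
        return out.reshape(x.shape[0], ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n = dy.shape[0]
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.grads["W"] = (dyf.T @ self._col).reshape(self.params["W"].shape)
        dcol = dyf @ self.params["W"].reshape(self.cout, -1)
        return _col2im(dcol, self._x_shape, self.k, self.k, self.stride,
                       self.pad, self._ho, self._wo)


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.state["running_mean"] = np.zeros(channels, dtype=DTYPE)
        self.state["running_var"] = np.ones(channels, dtype=DTYPE)

    def forward(self, x, training):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.state["running_mean"] = (
                m * self.state["running_mean"] + (1 - m) * mean).astype(DTYPE)
            self.state["running_var"] = (
                m * self.state["running_var"] + (1 - m) * var).astype(DTYPE)
        else:
            mean = self.state["running_mean"]
            var = self.state["running_var"]
        self._std = np.sqrt(var + self.eps).astype(DTYPE)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        return (g * self._xhat + b).astype(DTYPE)

    def backward(self, dy):
        axes = (0, 2, 3)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        # standard batch-norm backward through the batch statistics
        dx = (dxhat
              - dxhat.mean(axis=axes, keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True))
        return (dx / self._std[None, :, None, None]).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class MaxPool2D(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1) -> None:
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, training):
        n, c, h, w = x.shape
        self._x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]
        self._ho, self._wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, self._ho, self._wo, self.k * self.k)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._x_shape
        dwin = np.zeros((n, c, self._ho, self._wo, self.k * self.k), dtype=dy.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dy[..., None], axis=-1)
        dwin = dwin.reshape(n, c, self._ho, self._wo, self.k, self.k)
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=dy.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + self.stride * self._ho:self.stride,
                    j:j + self.stride * self._wo:self.stride] += dwin[:, :, :, :, i, j]
        return dxp[:, :, self.pad:self.pad + h, self.pad:self.pad + w]


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) feature vector."""

    def forward(self, x, training):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(
            dy[:, :, None, None] / self._hw, self._shape).astype(dy.dtype).copy()


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / cin), size=(cin, cout)).astype(DTYPE)
        self.params["b"] = np.zeros(cout, dtype=DTYPE)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ResidualBlock(Layer):
    """Two main-path Conv_BN_ReLU blocks plus a shortcut, added then ReLU'd."""

    def __init__(self, cin: int, cout: int, stride: int, projection: bool,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if not projection and (stride != 1 or cin != cout):
            raise ValueError("identity shortcut requires matching shape")
        self.main = [
            Conv2D(cin, cout, 3, stride, 1, rng), BatchNorm2D(cout), ReLU(),
            Conv2D(cout, cout, 3, 1, 1, rng), BatchNorm2D(cout),
        ]
        self.shortcut = (
            [Conv2D(cin, cout, 1, stride, 0, rng), BatchNorm2D(cout)]
            if projection else []
        )
        self.out_relu = ReLU()

    @property
    def sublayers(self) -> list[Layer]:
        return self.main + self.shortcut + [self.out_relu]

    def forward(self, x, training):
        y = x
        for layer in self.main:
            y = layer.forward(y, training)
        s = x
        for layer in self.shortcut:
            s = layer.forward(s, training)
        return self.out_relu.forward(y + s, training)

    def backward(self, dy):
        d = self.out_relu.backward(dy)
        dmain = d
        for layer in reversed(self.main):
            dmain = layer.backward(dmain)
        dshort = d
        for layer in reversed(self.shortcut):
            dshort = layer.backward(dshort)
        return dmain + dshort


class Network:
    """A sequential stack of layers ending in logits; softmax applied on top."""

    def __init__(self, layers: list[Layer], num_classes: int) -> None:
        self.layers = layers
        self.num_classes = num_classes

    def _flat_layers(self) -> Iterator[tuple[str, Layer]]:
        for i, layer in enumerate(self.layers):
            if isinstance(layer, ResidualBlock):
                for j, sub in enumerate(layer.sublayers):
                    yield f"layer{i}.sub{j}", sub
            else:
                yield f"layer{i}", layer

    def named_params(self) -> Iterator[tuple[str, Layer, str]]:
        for name, layer in self._flat_layers():
            for key in layer.params:
                yield f"{name}.{key}", layer, key

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class-probability matrix (rows on the simplex) for a batch."""
        y = np.asarray(x, dtype=DTYPE)
        if y.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {y.shape}")
        if y.shape[2] < 32 or y.shape[3] < 32:
            raise ValueError(
                f"input {y.shape[2]}x{y.shape[3]} too small: height and width "
                "must be >= 32 so the feature map survives the downsampling")
        for layer in self.layers:
            y = layer.forward(y, training)
        return softmax(y)

    predict_proba = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class indices; ties resolve to the lowest class index."""
        return np.argmax(self.forward(x, training=False), axis=1)

    def train_step(self, x: np.ndarray, y_onehot: np.ndarray) -> tuple[float, float]:
        """One forward/backward pass; returns (mean CE loss, batch accuracy)."""
        probs = self.forward(x, training=True)
        n = x.shape[0]
        loss = float(-np.mean(np.log(np.clip(
            (probs * y_onehot).sum(axis=1), 1e-12, None))))
        acc = float((probs.argmax(axis=1) == y_onehot.argmax(axis=1)).mean())
        dy = ((probs - y_onehot) / n).astype(DTYPE)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return loss, acc

    def parameter_total(self, include_bn_statistics: bool = True) -> int:
        """Realized parameter count from the actual arrays."""
        total = 0
        for _, layer in self._flat_layers():
            total += sum(p.size for p in layer.params.values())
            if include_bn_statistics:
                total += sum(s.size for s in layer.state.values())
        return total

    # -- serialization ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, layer in self._flat_layers():
            for key, arr in layer.params.items():
                out[f"{name}.{key}"] = arr
            for key, arr in layer.state.items():
                out[f"{name}.state.{key}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._flat_layers():
            for key in layer.params:
                layer.params[key] = np.asarray(state[f"{name}.{key}"], dtype=DTYPE)
            for key in layer.state:
                layer.state[key] = np.asarray(
                    state[f"{name}.state.{key}"], dtype=DTYPE)


class Adam:
    """Adam optimizer over all parameters of a :class:`Network`."""

    def __init__(self, net: Network, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 epsilon: float = 1e-8) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, epsilon
        self.t = 0
        self.m = {name: np.zeros_like(layer.params[key])
                  for name, layer, key in net.named_params()}
        self.v = {name: np.zeros_like(layer.params[key])
                  for name, layer, key in net.named_params()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for name, layer, key in self.net.named_params():
            g = layer.grads.get(key)
            if g is None:
                continue
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            layer.params[key] = (layer.params[key]
                                 - self.lr * (m / b1t)
                                 / (np.sqrt(v / b2t) + self.eps)).astype(DTYPE)
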