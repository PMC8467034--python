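"""Minimal NumPy neural-network core used by the reconstruction networks.

All tensors are channels-last: (batch, height, width, channels).  Every
convolutional kernel in the reconstruction networks has extent 1 along
height, so convolution, transposed convolution, max-pooling and bilinear
upsampling all act along the width axis only; the height axis is carried
through untouched.

Layers implement explicit ``forward``/``backward`` passes; transposed
convolution is realized as the exact adjoint of convolution (its forward
is the convolution input-gradient and vice versa), which keeps the two
operations consistent by construction.  Training is float64 and fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv",
    "Deconv",
    "MaxPool",
    "Bilinear",
    "Flatten",
    "Dense",
    "Dropout",
    "BatchNorm",
    "Tanh",
    "Sigmoid",
    "Relu",
    "Sequential",
    "Adam",
    "mae_loss",
]


def _same_pad(in_w: int, k: int, stride: int) -> tuple[int, int]:
    out_w = -(-in_w // stride)  # ceil
    total = max((out_w - 1) * stride + k - in_w, 0)
    return total // 2, total - total // 2


def conv_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int, pad: tuple[int, int]) -> np.ndarray:
    """x (B,H,W,C) * w (k,C,F) -> (B,H,W',F); loops over kernel taps."""
    k = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), pad, (0, 0))) if pad != (0, 0) else x
    wout = (xp.shape[2] - k) // stride + 1
    y = np.zeros(x.shape[:2] + (wout, w.shape[2]))
    for t in range(k):
        y += xp[:, :, t : t + stride * wout : stride, :] @ w[t]
    if b is not None:
        y += b
    return y


def conv_bwd_input(dy: np.ndarray, w: np.ndarray, stride: int, pad: tuple[int, int], in_w: int) -> np.ndarray:
    """Adjoint of conv_fwd with respect to its input."""
    k = w.shape[0]
    wout = dy.shape[2]
    dxp = np.zeros(dy.shape[:2] + (in_w + pad[0] + pad[1], w.shape[1]))
    for t in range(k):
        dxp[:, :, t : t + stride * wout : stride, :] += dy @ w[t].T
    if pad != (0, 0):
        return dxp[:, :, pad[0] : dxp.shape[2] - pad[1], :]
    return dxp


def conv_bwd_weights(x: np.ndarray, dy: np.ndarray, k: int, stride: int, pad: tuple[int, int]) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (0, 0), pad, (0, 0))) if pad != (0, 0) else x
    wout = dy.shape[2]
    dw = np.empty((k, x.shape[3], dy.shape[3]))
    dyf = dy.reshape(-1, dy.shape[3])
    for t in range(k):
        xs = xp[:, :, t : t + stride * wout : stride, :].reshape(-1, x.shape[3])
        dw[t] = xs.T @ dyf
    return dw


class Layer:
    """Base layer: parameter dict + cached forward state."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv(Layer):
    def __init__(self, k: int, c_in: int, c_out: int, stride: int = 1, padding: str = "valid", rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.stride = stride
        self.padding = padding
        self.params = {
            "w": _glorot(rng, (k, c_in, c_out), k * c_in, k * c_out),
            "b": np.zeros(c_out),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def _pad(self, in_w: int) -> tuple[int, int]:
        return _same_pad(in_w, self.k, self.stride) if self.padding == "same" else (0, 0)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return conv_fwd(x, self.params["w"], self.params["b"], self.stride, self._pad(x.shape[2]))

    def backward(self, dy):
        pad = self._pad(self._x.shape[2])
        self.grads["w"] = conv_bwd_weights(self._x, dy, self.k, self.stride, pad)
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return conv_bwd_input(dy, self.params["w"], self.stride, pad, self._x.shape[2])


class Deconv(Layer):
    """Transposed convolution: the exact adjoint of a Conv with the same
    kernel/stride/padding, mapping width W to (W-1)*stride + k ("valid")
    or W*stride ("same")."""

    def __init__(self, k: int, c_in: int, c_out: int, stride: int = 1, padding: str = "valid", rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.stride = stride
        self.padding = padding
        # weight laid out as the underlying conv kernel: (k, c_out, c_in)
        self.params = {
            "w": _glorot(rng, (k, c_out, c_in), k * c_in, k * c_out),
            "b": np.zeros(c_out),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def out_width(self, in_w: int) -> int:
        if self.padding == "same":
            return in_w * self.stride
        return (in_w - 1) * self.stride + self.k

    def _pad(self, out_w: int) -> tuple[int, int]:
        return _same_pad(out_w, self.k, self.stride) if self.padding == "same" else (0, 0)

    def forward(self, x, train=False, rng=None):
        self._x = x
        ow = self.out_width(x.shape[2])
        y = conv_bwd_input(x, self.params["w"], self.stride, self._pad(ow), ow)
        return y + self.params["b"]

    def backward(self, dy):
        ow = self.out_width(self._x.shape[2])
        pad = self._pad(ow)
        # forward was y = C(w)^T x, so dx = C(w) dy and dw pairs (dy, x)
        self.grads["w"] = conv_bwd_weights(dy, self._x, self.k, self.stride, pad)
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return conv_fwd(dy, self.params["w"], None, self.stride, pad)


class MaxPool(Layer):
    def __init__(self, k: int, stride: int = 1):
        super().__init__()
        self.k, self.stride = k, stride

    def forward(self, x, train=False, rng=None):
        win = sliding_window_view(x, self.k, axis=2)[:, :, :: self.stride]  # (B,H,W',C,k)
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        B, H, Wp, C = dy.shape
        dx = np.zeros(self._in_shape)
        b, h, wp, c = np.ix_(np.arange(B), np.arange(H), np.arange(Wp), np.arange(C))
        cols = self._arg + np.arange(Wp)[None, None, :, None] * self.stride
        np.add.at(dx, (b, h, cols, c), dy)
        return dx


class Bilinear(Layer):
    """Linear interpolation along width to a fixed target extent."""

    def __init__(self, out_w: int):
        super().__init__()
        self.out_w = out_w
        self._M = None
        self._in_w = None

    def _matrix(self, in_w: int) -> np.ndarray:
        if self._M is not None and self._in_w == in_w:
            return self._M
        M = np.zeros((self.out_w, in_w))
        if in_w == 1:
            M[:, 0] = 1.0
        else:
            pos = np.linspace(0.0, in_w - 1, self.out_w)
            lo = np.floor(pos).astype(int)
            hi = np.minimum(lo + 1, in_w - 1)
            frac = pos - lo
            M[np.arange(self.out_w), lo] += 1.0 - frac
            M[np.arange(self.out_w), hi] += frac
        self._M, self._in_w = M, in_w
        return M

    def forward(self, x, train=False, rng=None):
        M = self._matrix(x.shape[2])
        self._last_in = x.shape[2]
        return np.einsum("bhwc,vw->bhvc", x, M)

    def backward(self, dy):
        M = self._matrix(self._last_in)
        return np.einsum("bhvc,vw->bhwc", dy, M)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, units: int, rng: np.random.Generator | None = None, bias_init: float = 0.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        # a small positive bias_init keeps a following ReLU from dying
        # wholesale under sign-based (MAE) gradients on sparse targets
        self.params = {"w": _glorot(rng, (d_in, units), d_in, units), "b": np.full(units, float(bias_init))}
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads["w"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    """Per-channel normalization over (batch, height, width).

    Batch statistics during training, exponentially averaged running
    statistics (momentum 0.9) frozen at inference.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=False, rng=None):
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        self._n = x.shape[0] * x.shape[1] * x.shape[2]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = (0, 1, 2)
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        if not self._train:
            return dy * g / self._std
        n = self._n
        dxhat = dy * g
        return (dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class Tanh(Layer):
    def forward(self, x, train=False, rng=None):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Relu(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        """Yields (layer_index, name, array) for every trainable array."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield i, name, layer.params[name]

    def state_arrays(self) -> dict:
        """All arrays needed to reproduce the model (params + BN stats)."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                out[f"L{i}.{name}"] = p
            if isinstance(layer, BatchNorm):
                out[f"L{i}.running_mean"] = layer.running_mean
                out[f"L{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(state[f"L{i}.{name}"])
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(state[f"L{i}.running_mean"])
                layer.running_var = np.array(state[f"L{i}.running_var"])


class Adam:
    """Adaptive-moment optimizer with bias correction."""

    def __init__(self, model: Sequential, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {(i, n): np.zeros_like(p) for i, n, p in model.parameters()}
        self.v = {(i, n): np.zeros_like(p) for i, n, p in model.parameters()}

    def step(self) -> None:
        self.t += 1
        for i, name, p in self.model.parameters():
            g = self.model.layers[i].grads[name]
            key = (i, name)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g**2
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            self.model.layers[i].params[name] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient with respect to ``pred``."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad
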