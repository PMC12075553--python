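"""Minimal neural-network layer library (numpy, explicit backprop).

Implements exactly the components the two models in this package need:
fully-connected stacks with LeakyReLU for the WGAN pair, and
conv / batch-norm / ReLU / max-pool blocks with a sigmoid-gated spatial
attention, dropout and a linear head for the 1D CNN. Layers cache their
forward inputs and expose ``backward`` returning the gradient w.r.t. their
input; optimizers (RMSprop, Adam) update :class:`Param` objects in place.

All computation is float64 and single-threaded numpy, so runs are
bit-reproducible given the seeds. Gradients are verified against numeric
differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    """y = x @ W + b, He-initialized for (Leaky)ReLU stacks."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._x = None

    def forward(self, x, train):
        self._x = x
        return np.where(x > 0, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._x > 0, grad, self.slope * grad)


class ReLU(Layer):
    def __init__(self):
        self._x = None

    def forward(self, x, train):
        self._x = x
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return np.where(self._x > 0, grad, 0.0)


class Conv1d(Layer):
    """Same-padded 1D convolution on (N, C, L) maps; kernel must be odd."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        fan_in = c_in * kernel
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))
        self._windows = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._windows = sliding_window_view(xp, self.kernel, axis=2)  # (N,C,L,k)
        return (
            np.einsum("nclt,oct->nol", self._windows, self.w.value, optimize=True)
            + self.b.value[None, :, None]
        )

    def backward(self, grad):
        self.w.grad += np.einsum("nol,nclt->oct", grad, self._windows, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        # grad w.r.t. input = same-padded conv of grad with the flipped kernel
        p = self.kernel // 2
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p)))
        gwin = sliding_window_view(gp, self.kernel, axis=2)  # (N,O,L,k)
        wf = self.w.value[:, :, ::-1]
        return np.einsum("nolt,oct->ncl", gwin, wf, optimize=True)


class BatchNorm1d(Layer):
    """Per-channel batch norm over (N, L); tracks running inference stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train, x.shape[0] * x.shape[2])
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad):
        xhat, inv, train, m = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.value[None, :, None]
        if not train:
            return g * inv[None, :, None]
        gsum = g.sum(axis=(0, 2), keepdims=True)
        gx = (g * xhat).sum(axis=(0, 2), keepdims=True)
        return inv[None, :, None] * (g - gsum / m - xhat * gx / m)


class MaxPool1d(Layer):
    """Non-overlapping max pool with stride = window; trailing remainder dropped."""

    def __init__(self, window: int = 2):
        self.window = window
        self._cache = None

    def forward(self, x, train):
        n, c, length = x.shape
        lo = length // self.window
        if lo == 0:
            raise ValueError(f"length {length} shorter than pool window {self.window}")
        xv = x[:, :, : lo * self.window].reshape(n, c, lo, self.window)
        arg = xv.argmax(axis=3)
        self._cache = (x.shape, arg)
        return np.take_along_axis(xv, arg[..., None], axis=3)[..., 0]

    def backward(self, grad):
        shape, arg = self._cache
        n, c, length = shape
        lo = arg.shape[2]
        gx = np.zeros((n, c, lo, self.window))
        np.put_along_axis(gx, arg[..., None], grad[..., None], axis=3)
        out = np.zeros(shape)
        out[:, :, : lo * self.window] = gx.reshape(n, c, lo * self.window)
        return out

    def out_length(self, length: int) -> int:
        return length // self.window


class SpatialAttention(Layer):
    """Sigmoid gate over positions from channel mean/max pooling.

    Channel-wise mean and max (2 x L) pass through a same-padded 1D
    convolution and a sigmoid; the resulting map a(L) in (0,1) rescales
    every channel position: out[c, i] = x[c, i] * a[i].
    """

    def __init__(self, kernel: int, rng: np.random.Generator):
        self.conv = Conv1d(2, 1, kernel, rng)
        self._cache = None

    def params(self):
        return self.conv.params()

    def attention_map(self, x: np.ndarray) -> np.ndarray:
        pooled = np.stack([x.mean(axis=1), x.max(axis=1)], axis=1)
        pre = self.conv.forward(pooled, train=False)
        return 1.0 / (1.0 + np.exp(-pre))

    def forward(self, x, train):
        mean = x.mean(axis=1)
        argmax = x.argmax(axis=1)  # (N, L) winning channel per position
        mx = np.take_along_axis(x, argmax[:, None, :], axis=1)[:, 0, :]
        pooled = np.stack([mean, mx], axis=1)  # (N, 2, L)
        pre = self.conv.forward(pooled, train)
        a = 1.0 / (1.0 + np.exp(-pre))  # (N, 1, L)
        self._cache = (x, a, argmax)
        return x * a

    def backward(self, grad):
        x, a, argmax = self._cache
        n, c, length = x.shape
        gx = grad * a
        ga = (grad * x).sum(axis=1, keepdims=True)  # (N,1,L)
        gpre = ga * a * (1.0 - a)
        gpooled = self.conv.backward(gpre)  # (N,2,L)
        gx += gpooled[:, 0:1, :] / c
        gmax = np.zeros_like(x)
        np.put_along_axis(gmax, argmax[:, None, :], gpooled[:, 1:2, :], axis=1)
        return gx + gmax


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        """All parameter values plus batch-norm running stats, in layer order."""
        out = [p.value for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                out.extend([layer.running_mean, layer.running_var])
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        arrays = [np.asarray(a, dtype=np.float64) for a in arrays]
        params = self.params()
        if len(arrays) < len(params):
            raise ValueError("state array list too short")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.value.shape} vs {a.shape}")
            p.value = a.copy()
        extra = arrays[len(params) :]
        it = iter(extra)
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.maximum(probs[np.arange(n), y], 1e-300)).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class RMSprop:
    """RMSprop: v <- a*v + (1-a)*g^2; p <- p - lr*g/(sqrt(v)+eps)."""

    def __init__(self, params: list[Param], lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.v):
            v *= self.alpha
            v += (1.0 - self.alpha) * p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def clip_params(params: list[Param], c: float) -> None:
    """Project every parameter into [-c, c] (WGAN critic weight clipping)."""
    for p in params:
        np.clip(p.value, -c, c, out=p.value)
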