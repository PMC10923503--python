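"""Minimal pure-numpy neural-network engine for 1-D time-series classifiers.

Implements exactly the layer set the architectures in this package need
(dense, 1-D convolution, batch normalisation, pooling, dropout, residual
blocks) with manual backpropagation and an Adam optimiser.  Tensors follow
the ``(batch, channels, time)`` convention for convolutional layers and
``(batch, features)`` for dense layers.

The engine favours clarity over speed: convolutions use stride-tricks
windowing plus matrix multiplication, which is adequate for the segment
lengths and model widths used here on a single CPU.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: forward caches what backward needs; params is a list of
    [weight, grad] pairs shared with the optimiser."""

    params: list[list[np.ndarray]]

    def __init__(self) -> None:
        self.params = []

    def init(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.w = np.empty((n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [[self.w, self.dw], [self.b, self.db]]

    def init(self, rng: np.random.Generator) -> None:
        self.w[...] = rng.standard_normal(self.w.shape) * np.sqrt(2.0 / self.n_in)
        self.b[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T


class Conv1D(Layer):
    """1-D convolution (cross-correlation), stride 1, 'same' or 'valid' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: str = "same") -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"padding {padding!r}")
        self.c_in, self.c_out, self.kernel, self.padding = c_in, c_out, kernel, padding
        self.w = np.empty((c_out, c_in * kernel))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [[self.w, self.dw], [self.b, self.db]]

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.c_in * self.kernel
        self.w[...] = rng.standard_normal(self.w.shape) * np.sqrt(2.0 / fan_in)
        self.b[...] = 0.0

    def _pad(self) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        return (self.kernel - 1) // 2, self.kernel // 2

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pl, pr = self._pad()
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if pl or pr else x
        self._t_in, self._t_pad = x.shape[2], xp.shape[2]
        # (B, Cin, To, k) -> (B, To, Cin*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        b, _, t_out, _ = win.shape
        cols = win.transpose(0, 2, 1, 3).reshape(b, t_out, self.c_in * self.kernel)
        self._cols = cols
        y = cols @ self.w.T + self.b  # (B, To, Cout)
        return y.transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, _, t_out = grad.shape
        g = grad.transpose(0, 2, 1)  # (B, To, Cout)
        self.dw[...] = np.einsum("btc,btf->cf", g, self._cols)
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ self.w  # (B, To, Cin*k)
        dcols = dcols.reshape(b, t_out, self.c_in, self.kernel).transpose(0, 2, 3, 1)
        dxp = np.zeros((b, self.c_in, self._t_pad))
        for off in range(self.kernel):
            dxp[:, :, off : off + t_out] += dcols[:, :, off, :]
        pl, _ = self._pad()
        return dxp[:, :, pl : pl + self._t_in]


class BatchNorm(Layer):
    """Batch normalisation over (batch, time) per channel, or batch per feature."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = [[self.gamma, self.dgamma], [self.beta, self.dbeta]]
        self.run_mean = np.zeros(n_channels)
        self.run_var = np.ones(n_channels)
        self.momentum, self.eps = momentum, eps

    @staticmethod
    def _axes(x: np.ndarray) -> tuple[int, ...]:
        return (0, 2) if x.ndim == 3 else (0,)

    def _shape(self, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        return v[None, :, None] if x.ndim == 3 else v[None, :]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mean)) * self._shape(x, inv)
        self._xhat, self._inv, self._train = xhat, inv, train
        return self._shape(x, self.gamma) * xhat + self._shape(x, self.beta)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = self._axes(grad)
        m = np.prod([grad.shape[a] for a in axes])
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        g = grad * self._shape(grad, self.gamma)
        if not self._train:
            return g * self._shape(grad, self._inv)
        term = (
            g
            - self._shape(grad, g.sum(axis=axes)) / m
            - self._xhat * self._shape(grad, (g * self._xhat).sum(axis=axes)) / m
        )
        return term * self._shape(grad, self._inv)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(0)  # reseeded by Network.init

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class AvgPool1D(Layer):
    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, t = x.shape
        self._t = t
        t_out = t // self.pool
        self._t_used = t_out * self.pool
        return x[:, :, : self._t_used].reshape(b, c, t_out, self.pool).mean(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, t_out = grad.shape
        dx = np.zeros((b, c, self._t))
        dx[:, :, : self._t_used] = np.repeat(grad / self.pool, self.pool, axis=2)
        return dx


class MaxPool1D(Layer):
    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, t = x.shape
        self._t = t
        t_out = t // self.pool
        self._t_used = t_out * self.pool
        win = x[:, :, : self._t_used].reshape(b, c, t_out, self.pool)
        self._arg = win.argmax(axis=3)
        return win.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, t_out = grad.shape
        win = np.zeros((b, c, t_out, self.pool))
        bi, ci, ti = np.meshgrid(
            np.arange(b), np.arange(c), np.arange(t_out), indexing="ij"
        )
        win[bi, ci, ti, self._arg] = grad
        dx = np.zeros((b, c, self._t))
        dx[:, :, : self._t_used] = win.reshape(b, c, self._t_used)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._t, axis=2) / self._t


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Residual(Layer):
    """Residual block: ReLU(body(x) + shortcut(x)); identity shortcut if empty."""

    def __init__(self, body: list[Layer], shortcut: list[Layer] | None = None) -> None:
        super().__init__()
        self.body = body
        self.shortcut = shortcut or []
        for layer in self.body + self.shortcut:
            self.params.extend(layer.params)

    def init(self, rng: np.random.Generator) -> None:
        for layer in self.body + self.shortcut:
            layer.init(rng)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        for layer in self.body:
            h = layer.forward(h, train)
        s = x
        for layer in self.shortcut:
            s = layer.forward(s, train)
        self._mask = (h + s) > 0
        return (h + s) * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * self._mask
        gb = grad
        for layer in reversed(self.body):
            gb = layer.backward(gb)
        gs = grad
        for layer in reversed(self.shortcut):
            gs = layer.backward(gs)
        return gb + gs


class Adam:
    def __init__(self, params: list[list[np.ndarray]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A sequential network with a softmax or elementwise-sigmoid head.

    ``head='softmax'`` trains with categorical cross-entropy;
    ``head='sigmoid'`` with elementwise binary cross-entropy against the
    one-hot targets (prediction is argmax either way).
    """

    def __init__(self, layers: list[Layer], head: str = "softmax",
                 conv_input: bool = True) -> None:
        if head not in ("softmax", "sigmoid"):
            raise ValueError(f"head {head!r}")
        self.layers = layers
        self.head = head
        self.conv_input = conv_input
        self.params: list[list[np.ndarray]] = []
        for layer in layers:
            self.params.extend(layer.params)

    def init(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init(rng)
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(rng.integers(2**31))
        self._shuffle_rng = np.random.default_rng(seed + 1)

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        return x[:, None, :] if self.conv_input and x.ndim == 2 else x

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self._prepare(x)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def _loss_grad(self, logits: np.ndarray, y: np.ndarray) -> np.ndarray:
        n = logits.shape[0]
        onehot = np.zeros_like(logits)
        onehot[np.arange(n), y] = 1.0
        if self.head == "softmax":
            return (_softmax(logits) - onehot) / n
        p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
        return (p - onehot) / n

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int,
            batch_size: int = 16, lr: float = 1e-3) -> None:
        opt = Adam(self.params, lr=lr)
        n = x.shape[0]
        for _ in range(epochs):
            order = self._shuffle_rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self._forward(x[idx], train=True)
                grad = self._loss_grad(logits, y[idx])
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step()

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [
            self._forward(x[i : i + batch_size], train=False).argmax(axis=1)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out)
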