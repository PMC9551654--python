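"""Minimal CNN framework on NumPy (NCHW layout).

Implements exactly the layer set the lodging classifiers need — standard and
depthwise convolution, batch normalization, ReLU/ReLU6, max/average pooling,
dropout, linear — each with forward and backward passes, plus Adam and the
softmax cross-entropy loss.  Convolutions use im2col with stride-tricks
patch extraction; depthwise convolution has a dedicated vectorised path so
MobileNet-style networks train at usable speed on one CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Sequential", "Conv2d", "BatchNorm2d", "ReLU", "ReLU6",
    "MaxPool2d", "AdaptiveAvgPool2d", "Flatten", "Linear", "Dropout",
    "Residual", "Network", "Adam", "softmax_probs", "cross_entropy",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Ho, Wo, k, k) view of padded input xp."""
    w = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


class Conv2d(Layer):
    """2D convolution; ``groups`` must be 1 or equal to the channel count
    with out_channels == in_channels (depthwise)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, padding: int = 0,
                 groups: int = 1, bias: bool = True, rng: np.random.Generator | None = None):
        if groups not in (1, cin) or (groups == cin and cout != cin and groups != 1):
            raise ValueError("groups must be 1 or cin (depthwise)")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.padding, self.groups = stride, padding, groups
        rng = rng or np.random.default_rng()
        fan_in = (cin // groups) * k * k
        scale = np.sqrt(2.0 / fan_in)
        if groups == 1:
            wshape = (cout, cin, k, k)
        else:
            wshape = (cout, 1, k, k)
        self.weight = Param(rng.standard_normal(wshape, dtype=np.float32) * np.float32(scale))
        self.bias = Param(np.zeros(cout, dtype=np.float32)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train):
        N, C, H, W = x.shape
        p, s, k = self.padding, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = _windows(xp, k, s)  # (N, C, Ho, Wo, k, k)
        Ho, Wo = win.shape[2], win.shape[3]
        if self.groups == 1:
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
            wmat = self.weight.value.reshape(self.cout, C * k * k)
            out = cols @ wmat.T  # (N*Ho*Wo, cout)
            out = out.reshape(N, Ho, Wo, self.cout).transpose(0, 3, 1, 2)
            self._cache = (x.shape, cols, Ho, Wo)
        else:  # depthwise
            wdw = self.weight.value.reshape(C, k * k)
            wview = win.reshape(N, C, Ho, Wo, k * k)
            out = np.einsum("nchwk,ck->nchw", wview, wdw)
            self._cache = (x.shape, wview, Ho, Wo)
        if self.bias is not None:
            out = out + self.bias.value[None, :, None, None]
        return np.ascontiguousarray(out)

    def backward(self, grad):
        xshape, cache, Ho, Wo = self._cache
        N, C, H, W = xshape
        p, s, k = self.padding, self.stride, self.k
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        Hp, Wp = H + 2 * p, W + 2 * p
        dxp = np.zeros((N, C, Hp, Wp), dtype=grad.dtype)
        if self.groups == 1:
            cols = cache
            g2 = grad.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, self.cout)
            self.weight.grad += (g2.T @ cols).reshape(self.weight.value.shape)
            dcols = g2 @ self.weight.value.reshape(self.cout, C * k * k)
            dwin = dcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        else:
            wview = cache  # (N, C, Ho, Wo, k*k)
            self.weight.grad += np.einsum("nchw,nchwk->ck", grad, wview).reshape(
                self.weight.value.shape
            )
            wdw = self.weight.value.reshape(C, k * k)
            dwin = np.einsum("nchw,ck->nchwk", grad, wdw).reshape(N, C, Ho, Wo, k, k)
        # scatter-add window gradients back onto the (padded) input
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += dwin[
                    :, :, :, :, ki, kj
                ]
        return dxp[:, :, p : Hp - p, p : Wp - p] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.weight = Param(np.ones(c, dtype=np.float32))
        self.bias = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape) if train else None
        return self.weight.value[None, :, None, None] * xhat + self.bias.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.weight.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.weight.value[None, :, None, None]
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        inv4 = inv[None, :, None, None]
        return inv4 / m * (m * gxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class ReLU6(Layer):
    def forward(self, x, train):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0, 6)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, k: int, stride: int | None = None):
        self.k = k
        self.stride = stride if stride is not None else k

    def forward(self, x, train):
        N, C, H, W = x.shape
        k, s = self.k, self.stride
        win = _windows(x, k, s).reshape(N, C, -1, k * k)
        # flat index of the max inside each window
        self._arg = win.argmax(axis=3)
        self._xshape = x.shape
        Ho = (H - k) // s + 1
        Wo = (W - k) // s + 1
        self._ho, self._wo = Ho, Wo
        return win.max(axis=3).reshape(N, C, Ho, Wo)

    def backward(self, grad):
        N, C, H, W = self._xshape
        k, s = self.k, self.stride
        Ho, Wo = self._ho, self._wo
        dx = np.zeros((N, C, H, W), dtype=grad.dtype)
        g = grad.reshape(N, C, Ho * Wo)
        arg = self._arg  # (N, C, Ho*Wo)
        L = Ho * Wo
        li = np.arange(L)
        oi, oj = np.divmod(li, Wo)
        ki, kj = np.divmod(arg, k)
        rows = oi[None, None, :] * s + ki
        cols = oj[None, None, :] * s + kj
        n_idx = np.arange(N)[:, None, None]
        c_idx = np.arange(C)[None, :, None]
        np.add.at(dx, (n_idx, c_idx, rows, cols), g)
        return dx


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output size (input must divide evenly or
    exceed the target; uses equal integer bins like the common case)."""

    def __init__(self, out: int | tuple[int, int]):
        self.out = (out, out) if isinstance(out, int) else out

    def forward(self, x, train):
        N, C, H, W = x.shape
        oh, ow = self.out
        if H % oh or W % ow:
            raise ValueError(f"adaptive pool needs divisible sizes, got {H}x{W} -> {oh}x{ow}")
        self._xshape = x.shape
        bh, bw = H // oh, W // ow
        self._bins = (bh, bw)
        return x.reshape(N, C, oh, bh, ow, bw).mean(axis=(3, 5))

    def backward(self, grad):
        N, C, H, W = self._xshape
        oh, ow = self.out
        bh, bw = self._bins
        g = grad[:, :, :, None, :, None] / (bh * bw)
        return np.broadcast_to(g, (N, C, oh, bh, ow, bw)).reshape(N, C, H, W)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / fin)
        self.weight = Param(rng.standard_normal((fout, fin), dtype=np.float32) * np.float32(scale))
        self.bias = Param(np.zeros(fout, dtype=np.float32))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Dropout(Layer):
    def __init__(self, p: float = 0.5):
        self.p = p
        self.rng = np.random.default_rng()  # reseeded by the trainer

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Residual(Layer):
    """y = x + body(x); used by inverted-residual bottlenecks."""

    def __init__(self, body: Layer):
        self.body = body

    def params(self):
        return self.body.params()

    def forward(self, x, train):
        return x + self.body.forward(x, train)

    def backward(self, grad):
        return grad + self.body.backward(grad)


class Network:
    """A Sequential with bookkeeping for training (state save/restore)."""

    def __init__(self, body: Sequential, name: str = "net"):
        self.body = body
        self.name = name

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.body.forward(x.astype(np.float32), train)

    def backward(self, grad: np.ndarray) -> None:
        self.body.backward(grad)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    def _bn_layers(self) -> list[BatchNorm2d]:
        out = []

        def walk(layer):
            if isinstance(layer, BatchNorm2d):
                out.append(layer)
            for child in getattr(layer, "layers", []):
                walk(child)
            if isinstance(layer, Residual):
                walk(layer.body)

        walk(self.body)
        return out

    def dropout_layers(self) -> list[Dropout]:
        out = []

        def walk(layer):
            if isinstance(layer, Dropout):
                out.append(layer)
            for child in getattr(layer, "layers", []):
                walk(child)
            if isinstance(layer, Residual):
                walk(layer.body)

        walk(self.body)
        return out

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for bn in self._bn_layers():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        rest = state[len(ps):]
        for bn, (m, v) in zip(self._bn_layers(), zip(rest[::2], rest[1::2])):
            bn.running_mean[...] = m
            bn.running_var[...] = v


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient wrt the logits."""
    n = logits.shape[0]
    p = softmax_probs(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n
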