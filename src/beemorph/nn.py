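"""Minimal numpy neural-network engine with manual backpropagation.

Supports exactly what the segmentation and auto-crop networks need:
N-dimensional "same" convolutions (kernels per axis, stride 1), batch
normalisation, ReLU, max pooling, nearest-neighbour upsampling, dense heads,
global average pooling, dropout, softmax/sigmoid cross-entropy losses, and
SGD (with Nesterov momentum and iteration decay) and Adam optimisers.
Convolutions are evaluated as im2col + BLAS matmul; the input gradient of a
stride-1 same-padding convolution is itself such a convolution with the
spatially flipped, channel-transposed kernel.

All computation is deterministic given the seeds of the RNGs passed in, so
training histories are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .core import ConfigError


class Param:
    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = "", trainable: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _offsets(kernel):
    from itertools import product

    return list(product(*[range(k) for k in kernel]))


def _shift_slices(offs, kernel, spatial):
    """Output and source slice pairs realising a kernel-offset shift."""
    osl, ysl = [slice(None), slice(None)], [slice(None), slice(None)]
    for o, k, s in zip(offs, kernel, spatial):
        sh = o - (k - 1) // 2
        lo_o, hi_o = max(0, -sh), s - max(0, sh)
        if lo_o >= hi_o:
            return None, None
        osl.append(slice(lo_o, hi_o))
        ysl.append(slice(lo_o + sh, hi_o + sh))
    return tuple(osl), tuple(ysl)


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 same-padding cross-correlation.

    x: (N, C, *spatial); w: (Cout, C, *kernel); returns (N, Cout, *spatial).
    Evaluated as one matmul per kernel offset on the whole (contiguous)
    channels-first input, scattered into the shifted output window — this
    avoids materialising an im2col matrix.
    """
    kernel = w.shape[2:]
    spatial = x.shape[2:]
    n, c = x.shape[:2]
    xc = np.ascontiguousarray(np.moveaxis(x, 1, 0)).reshape(c, -1)
    wm = w.reshape(w.shape[0], c, -1)
    out = np.zeros((w.shape[0], n, *spatial), dtype=x.dtype)
    for m, offs in enumerate(_offsets(kernel)):
        osl, ysl = _shift_slices(offs, kernel, spatial)
        if osl is None:
            continue
        y = (wm[:, :, m] @ xc).reshape(-1, n, *spatial)
        out[osl] += y[ysl]
    return np.ascontiguousarray(np.moveaxis(out, 0, 1))


class Conv(Layer):
    """Same-padding convolution with per-axis odd kernel sizes, stride 1."""

    def __init__(self, c_in, c_out, kernel, rng, dtype=np.float32, name="conv"):
        self.kernel = tuple(kernel)
        if any(k % 2 == 0 for k in self.kernel):
            raise ConfigError("kernel sizes must be odd")
        fan_in = c_in * int(np.prod(self.kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, *self.kernel))
        self.w = Param(w.astype(dtype), f"{name}.w")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        out = _conv_same(x, self.w.value)
        out += self.b.value.reshape(1, -1, *([1] * len(self.kernel)))
        self._xc = (
            np.ascontiguousarray(np.moveaxis(x, 1, 0)) if train else None
        )  # (C, N, *spatial)
        return out

    def backward(self, dout):
        xc = self._xc
        c_out, c_in = self.w.value.shape[:2]
        nd = len(self.kernel)
        spatial = dout.shape[2:]
        dc = np.ascontiguousarray(np.moveaxis(dout, 1, 0))  # (Cout, N, *spatial)
        wg = self.w.grad.reshape(c_out, c_in, -1)
        for m, offs in enumerate(_offsets(self.kernel)):
            osl, ysl = _shift_slices(offs, self.kernel, spatial)
            if osl is None:
                continue
            a = np.ascontiguousarray(dc[osl]).reshape(c_out, -1)
            b = np.ascontiguousarray(xc[ysl]).reshape(c_in, -1)
            wg[:, :, m] += a @ b.T
        self.b.grad += dc.reshape(c_out, -1).sum(axis=1)
        # input gradient: convolve dout with flipped, channel-transposed kernel
        flip = (slice(None), slice(None)) + tuple(
            slice(None, None, -1) for _ in range(nd)
        )
        w_t = np.ascontiguousarray(
            self.w.value.transpose(1, 0, *range(2, 2 + nd))[flip]
        )
        dx = _conv_same(dout, w_t)
        self._xc = None
        return dx


class BatchNorm(Layer):
    def __init__(self, channels, nd, momentum=0.9, eps=1e-5, dtype=np.float32, name="bn"):
        self.gamma = Param(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._shape = (1, channels) + (1,) * nd
        self._axes = (0,) + tuple(range(2, 2 + nd))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(self._shape)) * inv.reshape(self._shape)
        self._cache = (xhat, inv) if train else None
        return self.gamma.value.reshape(self._shape) * xhat + self.beta.value.reshape(self._shape)

    def backward(self, dout):
        xhat, inv = self._cache
        n = dout.size // dout.shape[1]
        self.gamma.grad += (dout * xhat).sum(axis=self._axes)
        self.beta.grad += dout.sum(axis=self._axes)
        g = self.gamma.value.reshape(self._shape)
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=self._axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=self._axes, keepdims=True) / n
        ) * inv.reshape(self._shape)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool(Layer):
    """Max pooling by integer factors per spatial axis (shape must divide)."""

    def __init__(self, factors):
        self.factors = tuple(factors)

    def forward(self, x, train):
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        f = self.factors
        outs = tuple(s // fi for s, fi in zip(spatial, f))
        if any(s % fi for s, fi in zip(spatial, f)):
            raise ConfigError(f"spatial shape {spatial} not divisible by pool {f}")
        shape = (n, c) + tuple(v for o, fi in zip(outs, f) for v in (o, fi))
        xr = x.reshape(shape)
        nd = len(f)
        order = (0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(3 + 2 * i for i in range(nd))
        xr = xr.transpose(order).reshape(n, c, *outs, -1)
        self._idx = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c = dout.shape[:2]
        outs = dout.shape[2:]
        f = self.factors
        nd = len(f)
        flat = np.zeros((n, c, *outs, int(np.prod(f))), dtype=dout.dtype)
        np.put_along_axis(flat, self._idx[..., None], dout[..., None], axis=-1)
        flat = flat.reshape(n, c, *outs, *f)
        inv = (0, 1) + tuple(
            2 + i + (nd if j else 0) for i in range(nd) for j in (0, 1)
        )
        return flat.transpose(inv).reshape(self._inshape)


class Upsample(Layer):
    """Nearest-neighbour upsampling by integer factors per spatial axis."""

    def __init__(self, factors):
        self.factors = tuple(factors)

    def forward(self, x, train):
        out = x
        for ax, fi in enumerate(self.factors):
            out = out.repeat(fi, axis=2 + ax)
        self._inshape = x.shape
        return out

    def backward(self, dout):
        n, c = dout.shape[:2]
        ins = self._inshape[2:]
        f = self.factors
        nd = len(f)
        shape = (n, c) + tuple(v for i, fi in zip(ins, f) for v in (i, fi))
        return dout.reshape(shape).sum(axis=tuple(3 + 2 * i for i in range(nd)))


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dout):
        spatial = self._shape[2:]
        scale = 1.0 / float(np.prod(spatial))
        return np.broadcast_to(
            dout.reshape(dout.shape + (1,) * len(spatial)) * scale, self._shape
        ).copy()


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float32, name="dense"):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.w = Param(w.astype(dtype), f"{name}.w")
        self.b = Param(np.zeros(n_out, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout):
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Dropout(Layer):
    def __init__(self, p, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


# losses ---------------------------------------------------------------------


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean voxel-wise categorical cross-entropy.

    logits: (N, L, *spatial); targets: integer class ids (N, *spatial).
    Returns (loss, dlogits, accuracy).
    """
    p = softmax(logits, axis=1)
    n_vox = targets.size
    idx = np.expand_dims(targets, 1)
    picked = np.take_along_axis(p, idx, axis=1)
    loss = float(-np.log(np.clip(picked, 1e-12, None)).sum() / n_vox)
    grad = p.copy()
    np.put_along_axis(grad, idx, picked - 1.0, axis=1)
    grad /= n_vox
    acc = float((logits.argmax(axis=1) == targets).mean())
    return loss, grad.astype(logits.dtype), acc


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def binary_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean BCE with logits; returns (loss, dlogits, accuracy)."""
    p = sigmoid(logits)
    n = targets.size
    eps = 1e-12
    loss = float(-(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps)).sum() / n)
    grad = ((p - targets) / n).astype(logits.dtype)
    acc = float(((p >= 0.5) == (targets >= 0.5)).mean())
    return loss, grad, acc


# optimisers -----------------------------------------------------------------


class SGD:
    """SGD with momentum, optional Nesterov, and 1/(1+decay*t) learning-rate decay."""

    def __init__(self, params, lr=0.01, momentum=0.9, nesterov=True, decay=1e-6):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self.decay = decay
        self.iterations = 0
        self._vel = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        lr = self.lr / (1.0 + self.decay * self.iterations)
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v -= lr * p.grad
            if self.nesterov:
                p.value += self.momentum * v - lr * p.grad
            else:
                p.value += v
        self.iterations += 1

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def get_weights(layer: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in layer.params()]


def set_weights(layer: Layer, weights: list[np.ndarray]) -> None:
    for p, w in zip(layer.params(), weights, strict=True):
        p.value = w.copy()
        p.grad = np.zeros_like(p.value)
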