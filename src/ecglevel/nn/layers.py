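"""Minimal NumPy layers with manual backpropagation.

Only what the regression network needs: 1-D "same" convolution (im2col +
BLAS matmul), a lead-combining convolution across the 12-lead axis, batch
normalization, ReLU, temporal max pooling, dense layers, dropout, and Adam.
All activations are float32.  Every layer caches what its backward pass
needs; gradients are accumulated into ``g<name>`` attributes consumed by
the optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    trainable: tuple[str, ...] = ()

    def params(self):
        return [(self, name) for name in self.trainable]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Temporal convolution with zero ("same") padding on (M, C, T) input.

    ``stride`` implements the per-layer temporal downsampling factor (the
    output keeps every ``stride``-th position).  ``needs_dx`` lets the first
    layer of a network skip the input-gradient computation, which is by far
    its most expensive part and is unused at the input.
    """

    trainable = ("W", "b")

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 needs_dx: bool = True):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.needs_dx = stride, needs_dx
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel - 1 - self.pad_l
        self.W = xavier_uniform(rng, (out_ch, in_ch, kernel),
                                fan_in=in_ch * kernel, fan_out=out_ch * kernel)
        self.b = np.zeros(out_ch, dtype=F32)

    def out_length(self, t: int) -> int:
        return (t + self.stride - 1) // self.stride

    def forward(self, x, train):
        m, c, t = x.shape
        s = self.stride
        t_out = self.out_length(t)
        # pad so every strided window is complete
        extra = (t_out - 1) * s + self.kernel - (t + self.pad_l + self.pad_r)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r + max(extra, 0))))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)) \
            .reshape(m * t_out, c * self.kernel)
        self._shape = (m, c, t, t_out)
        if train:
            self._cols = cols
        y = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        return np.ascontiguousarray(y.reshape(m, t_out, self.out_ch)
                                    .transpose(0, 2, 1))

    def backward(self, dy):
        m, c, t, t_out = self._shape
        k, s = self.kernel, self.stride
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(m * t_out,
                                                                  self.out_ch)
        self.gW = (dyr.T @ self._cols).reshape(self.W.shape)
        self.gb = dyr.sum(axis=0)
        self._cols = None
        if not self.needs_dx:
            return None
        dcols = (dyr @ self.W.reshape(self.out_ch, -1)) \
            .reshape(m, t_out, c, k).transpose(0, 2, 1, 3)       # (M, C, T', K)
        pad_t = self.pad_l + max(t + self.pad_r, (t_out - 1) * s + k - self.pad_l)
        dxp = np.zeros((m, c, pad_t), dtype=F32)
        for j in range(k):
            dxp[:, :, j:j + (t_out - 1) * s + 1:s] += dcols[:, :, :, j]
        return dxp[:, :, self.pad_l:self.pad_l + t]


class LeadConv(Layer):
    """[leads x 1] convolution combining the 12 leads: (N, C, L, T) -> (N, O, T)."""

    trainable = ("W", "b")

    def __init__(self, in_ch: int, leads: int, out_ch: int,
                 rng: np.random.Generator):
        self.leads = leads
        self.W = xavier_uniform(rng, (out_ch, in_ch, leads),
                                fan_in=in_ch * leads, fan_out=out_ch)
        self.b = np.zeros(out_ch, dtype=F32)

    def forward(self, x, train):
        self._x = x
        y = np.einsum("nclt,ocl->not", x, self.W, optimize=True)
        return (y + self.b[None, :, None]).astype(F32)

    def backward(self, dy):
        self.gW = np.einsum("not,nclt->ocl", dy, self._x, optimize=True)
        self.gb = dy.sum(axis=(0, 2))
        dx = np.einsum("not,ocl->nclt", dy, self.W, optimize=True).astype(F32)
        self._x = None
        return dx


class BatchNorm(Layer):
    """Normalize over every axis except channel axis 1."""

    trainable = ("gamma", "beta")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, train):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * ivar.reshape(shape)
        if train:
            self._xhat, self._ivar, self._axes = xhat, ivar, axes
        return (self.gamma.reshape(shape) * xhat
                + self.beta.reshape(shape)).astype(F32)

    def backward(self, dy):
        axes, shape = self._axes, self._bshape(dy.ndim)
        m = dy.size // dy.shape[1]
        self.gbeta = dy.sum(axis=axes)
        self.ggamma = (dy * self._xhat).sum(axis=axes)
        coef = (self.gamma * self._ivar / m).reshape(shape)
        dx = coef * (m * dy
                     - self.gbeta.reshape(shape)
                     - self._xhat * self.ggamma.reshape(shape))
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy):
        return np.where(self._mask, dy, F32(0.0))


class MaxPool1d(Layer):
    """Temporal max pooling by an integer factor on (M, C, T)."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, train):
        f = self.factor
        m, c, t = x.shape
        t2 = t // f
        xr = x[:, :, :t2 * f].reshape(m, c, t2, f)
        self._arg = xr.argmax(axis=3)
        self._in_t = t
        return xr.max(axis=3)

    def backward(self, dy):
        f = self.factor
        m, c, t2 = dy.shape
        dxr = np.zeros((m, c, t2, f), dtype=F32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros((m, c, self._in_t), dtype=F32)
        dx[:, :, :t2 * f] = dxr.reshape(m, c, t2 * f)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    trainable = ("W", "b")

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = xavier_uniform(rng, (n_in, n_out), fan_in=n_in, fan_out=n_out)
        self.b = np.zeros(n_out, dtype=F32)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.gW = self._x.T @ dy
        self.gb = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / F32(1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Adam:
    """Adam over a list of (layer, attribute-name) parameter handles."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, n)) for l, n in params]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in params]
        self.t = 0

    def step(self):
        self.t += 1
        corr1 = 1 - self.b1 ** self.t
        corr2 = 1 - self.b2 ** self.t
        for i, (layer, name) in enumerate(self.params):
            g = getattr(layer, "g" + name).astype(F32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / corr1
            vhat = self.v[i] / corr2
            w = getattr(layer, name)
            setattr(layer, name,
                    (w - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32))
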