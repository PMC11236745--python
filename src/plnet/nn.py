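"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the primitives the segmentation network needs:
2D convolution (kernel 1 or 3, stride 1), stride-2 transposed convolution,
2x2 max pooling, batch normalization, ReLU/sigmoid/softmax, channel
concatenation, elementwise arithmetic and reductions, plus an Adam optimizer.

Tensors hold ``float64`` data in NCHW layout (reductions may be 0-d).  The
graph is a tape of parent links; :meth:`Tensor.backward` runs a topological
sweep.  Everything is plain single-threaded numpy, so runs are bitwise
reproducible for a fixed seed on a given machine.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "maxpool2x2",
    "relu",
    "sigmoid",
    "softmax_channel",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ConvUnit",
    "TransposeUp",
    "Adam",
    "kaiming_normal",
]


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def detach(self):
        return Tensor(self.data.copy())


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Parameter(Tensor):
    """A trainable tensor with a name (used for checkpoints and counting)."""

    __slots__ = ("name",)

    def __init__(self, data, name=""):
        super().__init__(data, requires_grad=True)
        self.name = name


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------


def concat(tensors, axis=1):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def _windows(x, k):
    """Sliding kxk windows of a padded NCHW array -> (N, C, H, W, k, k)."""
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    return np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))


def conv2d(x, weight, bias=None):
    """'Same' convolution, stride 1.  weight: (Cout, Cin, k, k), k in {1, 3}."""
    k = weight.data.shape[-1]
    win = _windows(x.data, k)
    y = np.einsum("nchwij,ocij->nohw", win, weight.data, optimize=True)
    if bias is not None:
        y = y + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents=parents)

    def bwd(g):
        if weight.requires_grad:
            gw = np.einsum("nchwij,nohw->ocij", win, g, optimize=True)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gwin = _windows(g, k)
            wflip = weight.data[:, :, ::-1, ::-1]
            gx = np.einsum("nohwij,ocij->nchw", gwin, wflip, optimize=True)
            x._accumulate(gx)

    out._backward = bwd
    return out


# Valid (i, output-row-parity) index ranges per kernel tap for the stride-2
# transposed conv: output[2i + d - 1] receives tap d of input row i.
def _tap_slices(d, n_in):
    if d == 0:
        return slice(1, n_in), slice(1, 2 * n_in - 2, 2)
    if d == 1:
        return slice(0, n_in), slice(0, 2 * n_in - 1, 2)
    return slice(0, n_in), slice(1, 2 * n_in, 2)


def conv_transpose2d(x, weight, bias=None):
    """Stride-2 transposed conv, kernel 3, pad 1, output pad 1 (doubles H, W).

    weight: (Cin, Cout, 3, 3).
    """
    n, ci, h, w = x.data.shape
    co = weight.data.shape[1]
    y = np.zeros((n, co, 2 * h, 2 * w))
    for di in range(3):
        si, so = _tap_slices(di, h)
        for dj in range(3):
            sj, tj = _tap_slices(dj, w)
            t = np.einsum(
                "nchw,co->nohw", x.data[:, :, si, sj], weight.data[:, :, di, dj],
                optimize=True,
            )
            y[:, :, so, tj] += t
    if bias is not None:
        y += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents=parents)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        gw = np.zeros_like(weight.data) if weight.requires_grad else None
        for di in range(3):
            si, so = _tap_slices(di, h)
            for dj in range(3):
                sj, tj = _tap_slices(dj, w)
                gpart = g[:, :, so, tj]
                if gx is not None:
                    gx[:, :, si, sj] += np.einsum(
                        "nohw,co->nchw", gpart, weight.data[:, :, di, dj],
                        optimize=True,
                    )
                if gw is not None:
                    gw[:, :, di, dj] += np.einsum(
                        "nchw,nohw->co", x.data[:, :, si, sj], gpart,
                        optimize=True,
                    )
        if gx is not None:
            x._accumulate(gx)
        if gw is not None:
            weight._accumulate(gw)

    out._backward = bwd
    return out


def maxpool2x2(x):
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gflat = np.zeros((n, c, h // 2, w // 2, 4))
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5
            ).reshape(n, c, h, w)
            x._accumulate(gx)

    out._backward = bwd
    return out


def relu(x):
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = bwd
    return out


def sigmoid(x):
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


def softmax_channel(x):
    """Softmax over the channel axis of an NCHW tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=1, keepdims=True)
            x._accumulate(s * (g - dot))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


def kaiming_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Base class: children discovered by attribute scan, lists included."""

    def named_parameters(self, prefix=""):
        out = []

        def visit(name, val):
            if isinstance(val, Parameter):
                val.name = name
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=name + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    visit(f"{name}.{i}", item)

        for key, val in vars(self).items():
            visit(f"{prefix}{key}", val)
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def buffers(self):
        out = []

        def visit(val):
            if isinstance(val, Module):
                out.extend(val.buffers())
            elif isinstance(val, (list, tuple)):
                for item in val:
                    visit(item)

        for key, val in vars(self).items():
            if key in ("running_mean", "running_var"):
                out.append((self, key))
            else:
                visit(val)
        return out


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, bias=True):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            kaiming_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    def __init__(self, in_ch, out_ch, rng):
        fan_in = in_ch * 9
        self.weight = Parameter(kaiming_normal(rng, (in_ch, out_ch, 3, 3), fan_in))
        self.bias = Parameter(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch

    def __call__(self, x):
        return conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, train):
        if train:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat
        y = y + self.beta.data[None, :, None, None]
        out = Tensor(y, parents=(x, self.gamma, self.beta))
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def bwd(g):
            if self.gamma.requires_grad:
                self.gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if self.beta.requires_grad:
                self.beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = g * self.gamma.data[None, :, None, None]
                if train:
                    gx = (
                        gi
                        - gi.mean(axis=(0, 2, 3), keepdims=True)
                        - xhat * (gi * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                    ) * inv[None, :, None, None]
                else:
                    gx = gi * inv[None, :, None, None]
                x._accumulate(gx)

        out._backward = bwd
        return out


class ConvUnit(Module):
    """3x3 (or 1x1) conv + batch norm + ReLU — the basic building unit."""

    def __init__(self, in_ch, out_ch, rng, kernel=3):
        self.conv = Conv2d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm2d(out_ch)
        self.in_ch, self.out_ch = in_ch, out_ch

    def __call__(self, x, train):
        return relu(self.bn(self.conv(x), train))


class TransposeUp(Module):
    """Channel-preserving stride-2 transposed conv + batch norm + ReLU."""

    def __init__(self, ch, rng):
        self.up = ConvTranspose2d(ch, ch, rng)
        self.bn = BatchNorm2d(ch)

    def __call__(self, x, train):
        return relu(self.bn(self.up(x), train))


class Adam:
    """Adam with bias correction; first-moment decay beta1 defaults to 0.9."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
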