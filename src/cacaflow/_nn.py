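"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical engine behind :mod:`cacaflow.net` and
:mod:`cacaflow.train`: a tape-based autograd ``Tensor`` plus the handful of
layers a residual encoder / U-Net decoder needs (2D convolution via
im2col, batch normalization, ReLU, bilinear upsampling, linear layers) and
an Adam optimizer.  Everything runs in float32 on a single CPU thread and
is deterministic for a fixed parameter initialization and data order,
which the training contracts rely on.

Only the operations the package uses are implemented; this is not a
general-purpose framework.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


# ---------------------------------------------------------------------------
# Tensor and tape
# ---------------------------------------------------------------------------

class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.ascontiguousarray(data, dtype=_F32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar or any-shape seed-of-ones) tensor."""
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(-1)[0])


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Primitive ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def back(g):
        a._accumulate(g)
        b._accumulate(g)
    return _node(a.data + b.data, (a, b), back)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g):
        x._accumulate(g * mask)
    return _node(x.data * mask, (x,), back)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def back(g):
        x._accumulate(g * y * (1.0 - y))
    return _node(y, (x,), back)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]

    def back(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])
    return _node(np.concatenate([a.data, b.data], axis=1), (a, b), back)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape

    def back(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))
    return _node(x.data.mean(axis=(2, 3)), (x,), back)


def mul_const(x: Tensor, c: np.ndarray) -> Tensor:
    """Elementwise product with a constant array (no gradient through c)."""
    c = np.asarray(c, dtype=_F32)

    def back(g):
        x._accumulate(g * c)
    return _node(x.data * c, (x,), back)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def back(g):
        x._accumulate(np.full(x.data.shape, float(np.asarray(g).flat[0]) / n, dtype=_F32))
    return _node(np.asarray(x.data.mean()), (x,), back)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores (numerically stable)."""
    z = logits.data
    t = np.asarray(targets, dtype=_F32).reshape(z.shape)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    n = z.size

    def back(g):
        logits._accumulate(float(np.asarray(g).flat[0]) * (p - t) / n)
    return _node(np.asarray(loss.mean()), (logits,), back)


# ---------------------------------------------------------------------------
# Convolution (im2col) and bilinear upsampling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=_F32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(gcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    g6 = gcols.reshape(n, c, kh, kw, oh, ow)
    gxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=_F32)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += g6[:, :, i, j]
    return gxp[:, :, pad:pad + h, pad:pad + w] if pad else gxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    cout, cin, kh, kw = w.data.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    w2 = w.data.reshape(cout, -1)
    out = np.matmul(w2, cols)                       # (n, cout, oh*ow)
    if b is not None:
        out += b.data[None, :, None]
    n = x.data.shape[0]

    def back(g):
        g2 = g.reshape(n, cout, oh * ow)
        w._accumulate(np.einsum("ncl,nkl->ck", g2, cols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(g2.sum(axis=(0, 2)))
        gcols = np.matmul(w2.T, g2)                 # (n, k, oh*ow)
        x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, pad))
    return _node(out.reshape(n, cout, oh, ow), (x, w, b), back)


def _upsample_matrix(size_in: int, scale: int) -> np.ndarray:
    """Dense (scale*size_in, size_in) bilinear interpolation matrix
    (half-pixel centers, edges clamped)."""
    size_out = size_in * scale
    src = (np.arange(size_out) + 0.5) / scale - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, size_in - 1)
    i1 = np.clip(i0 + 1, 0, size_in - 1)
    w1 = np.clip(src - np.floor(src), 0.0, 1.0)
    w1[src < 0] = 0.0
    m = np.zeros((size_out, size_in), dtype=_F32)
    m[np.arange(size_out), i0] += (1.0 - w1)
    m[np.arange(size_out), i1] += w1
    return m


_UP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def upsample_bilinear2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    mh = _UP_CACHE.setdefault((h, 2), _upsample_matrix(h, 2))
    mw = _UP_CACHE.setdefault((w, 2), _upsample_matrix(w, 2))
    flat = x.data.reshape(n * c, h, w)
    y = np.matmul(mh[None], flat)            # (n*c, 2h, w)
    y = np.matmul(y, mw.T[None])             # (n*c, 2h, 2w)

    def back(g):
        gf = g.reshape(n * c, 2 * h, 2 * w)
        gx = np.matmul(gf, mw[None])
        gx = np.matmul(mh.T[None], gx)
        x._accumulate(gx.reshape(x.data.shape))
    return _node(y.reshape(n, c, 2 * h, 2 * w), (x,), back)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: tracks parameters and train/eval mode recursively."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    training = True

    # -- serialization ----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and running-statistic arrays, in a stable order."""
        arrs = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrs.extend([m.running_mean, m.running_var])
        return arrs


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=0, bias=True, *, rng):
        fan_in = cin * k * k
        bound = float(np.sqrt(2.0 / fan_in))  # He initialization
        self.weight = Tensor(rng.normal(0.0, bound, size=(cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.eps, self.momentum = eps, momentum

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.data.mean(axis=(0, 2, 3))
            v = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (m - self.running_mean)
            self.running_var += self.momentum * (v - self.running_var)
        else:
            m, v = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(v + self.eps)
        xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        gamma, beta, training = self.gamma, self.beta, self.training
        n_elem = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def back(g):
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            gi = g * gamma.data[None, :, None, None]
            if training:
                # full batch-norm backward (statistics depend on x)
                gx = (gi - gi.mean(axis=(0, 2, 3), keepdims=True)
                      - xhat * (gi * xhat).sum(axis=(0, 2, 3), keepdims=True) / n_elem)
                gx *= inv[None, :, None, None]
            else:
                gx = gi * inv[None, :, None, None]
            x._accumulate(gx.astype(_F32))
        return _node(out, (x, self.gamma, self.beta), back)


class Linear(Module):
    def __init__(self, cin, cout, *, rng):
        bound = float(np.sqrt(1.0 / cin))
        self.weight = Tensor(rng.uniform(-bound, bound, size=(cout, cin)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        out = x.data @ w.data.T + b.data

        def back(g):
            w._accumulate(g.T @ x.data)
            b._accumulate(g.sum(axis=0))
            x._accumulate(g @ w.data)
        return _node(out, (x, w, b), back)


class ConvBnRelu(Module):
    def __init__(self, cin, cout, k, stride=1, pad=0, *, rng):
        self.conv = Conv2d(cin, cout, k, stride, pad, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))


class BasicBlock(Module):
    """Residual unit: two 3x3 conv/BN with identity (or 1x1-projected) shortcut."""

    def __init__(self, cin, cout, stride=1, *, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride, 0, bias=False, rng=rng)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        y = relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        shortcut = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return relu(add(y, shortcut))


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
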