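"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core for every trainable model in the package: the
contrastive tile encoder, the transformer bag aggregator and the specimen
CNN. It supports exactly the operations those models need (dense algebra,
batched matmul, softmax building blocks, im2col convolution) plus an Adam
optimizer. Everything is float64 and fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "concat",
    "softmax",
    "layer_norm",
    "softplus",
    "conv2d",
    "avg_pool2d",
    "Adam",
    "init_linear",
]


class Tensor:
    """Node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    # -- graph bookkeeping ---------------------------------------------
    def _needs_graph(self, *others):
        return self.requires_grad or any(o.requires_grad for o in others)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + g

    # -- elementwise binary ops ----------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), bwd)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), bwd)

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * _as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other) * self.pow(-1.0)

    __radd__ = __add__
    __rmul__ = __mul__

    def pow(self, exponent: float):
        out_data = self.data ** exponent

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), bwd)

    def sqrt(self):
        return self.pow(0.5)

    # -- matmul ---------------------------------------------------------
    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), bwd)

    # -- unary ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(out_data, (self,), bwd)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        return self._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape))

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return self._make(out_data, (self,), bwd)

    def transpose(self, axes):
        out_data = np.transpose(self.data, axes)
        inverse = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.transpose(g, inverse))

        return self._make(out_data, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return self._make(out_data, (self,), bwd)

    # ---------------------------------------------------------------------
    def _make(self, data, parents, backward):
        if any(p.requires_grad for p in parents):
            out = Tensor(data, requires_grad=True, parents=parents, backward=backward)
        else:
            out = Tensor(data)
        return out

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def constant(data):
    return Tensor(data)


def parameter(data):
    return Tensor(data, requires_grad=True)


def concat(tensors, axis=0):
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    if any(t.requires_grad for t in tensors):
        return Tensor(out_data, requires_grad=True, parents=tuple(tensors), backward=bwd)
    return Tensor(out_data)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = constant(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * gain + bias


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable (primitive op)."""
    out_data = np.logaddexp(0.0, x.data)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * _sigmoid(x.data))

    return x._make(out_data, (x,), bwd)


# ---------------------------------------------------------------------------
# convolution via im2col
# ---------------------------------------------------------------------------

def _im2col(x: Tensor, k: int, pad: int) -> Tensor:
    """(B,H,W,C) -> (B,H,W,k*k*C) patches with zero padding (stride 1)."""
    B, H, W, C = x.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (B, H', W', C, k, k) with H' = H + 2p - k + 1
    Ho, Wo = win.shape[1], win.shape[2]
    col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(B, Ho, Wo, k * k * C)

    def bwd(g):
        if not x.requires_grad:
            return
        gk = g.reshape(B, Ho, Wo, k, k, C)
        full = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                full[:, di:di + Ho, dj:dj + Wo, :] += gk[:, :, :, di, dj, :]
        if pad:
            full = full[:, pad:-pad, pad:-pad, :]
        x._accumulate(full)

    return x._make(col, (x,), bwd)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int = 1) -> Tensor:
    """Stride-1 2-D convolution; x (B,H,W,Cin), weight (k*k*Cin, Cout)."""
    k = int(round((weight.shape[0] // x.shape[-1]) ** 0.5))
    col = _im2col(x, k, pad)
    return col @ weight + bias


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    """(B,H,W,C) average pooling; H and W must be divisible by factor."""
    B, H, W, C = x.shape
    f = factor
    if H % f or W % f:
        raise ValueError("pooling factor must divide spatial dims")
    y = x.reshape(B, H // f, f, W // f, f, C)
    return y.mean(axis=(2, 4))


# ---------------------------------------------------------------------------
# initialization and optimizer
# ---------------------------------------------------------------------------

def init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    """Glorot-uniform weight and zero bias as parameter Tensors."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    w = parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
    b = parameter(np.zeros(fan_out))
    return w, b


class Adam:
    """Adam optimizer over a name -> Tensor parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
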