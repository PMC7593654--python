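"""Minimal reverse-mode autodiff and neural-network layers.

A compact tape-based engine on numpy arrays providing exactly the
operations the reconstruction networks need: dense layers, 3x3 same
convolutions, 2x2 max-pooling, 2x2 stride-2 transposed convolutions,
ReLU / ELU nonlinearities, channel concatenation, and the Adam
optimizer.  A layer is an affine map composed with a pointwise
nonlinearity; convolutional layers share their filter weights across
space.

Arrays are float64 throughout so that the degenerate-network
equivalence contracts (e.g. a residual block acting as a plain gradient
step) hold to near machine precision.  Shapes follow the (batch,
channel, height, width) convention.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "Parameter", "no_grad", "add", "sub", "scale", "matmul",
    "relu", "elu", "reshape", "concat_channels", "conv2d",
    "conv_transpose2d", "maxpool2d", "mse_loss", "Module", "Linear",
    "Conv2d", "ConvTranspose2d", "Adam", "he_init",
]

_GRAD_ENABLED = [True]
_DTYPE = [np.float64]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (for frozen-network evaluation)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


@contextlib.contextmanager
def default_dtype(dtype):
    """Set the working precision for tensors created in this scope.

    float64 (the default) is used wherever exact degenerate-network
    contracts matter; float32 roughly halves training time and is the
    conventional precision for network training.
    """
    _DTYPE.append(np.dtype(dtype))
    try:
        yield
    finally:
        _DTYPE.pop()


class Tensor:
    """Node of the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE[-1])
        self.grad = None
        self._parents = parents if _GRAD_ENABLED[-1] else ()
        self._backward = backward if _GRAD_ENABLED[-1] else None

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Reverse sweep from this (scalar) node."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        self.grad = g if self.grad is None else self.grad + g


class Parameter(Tensor):
    """A named leaf tensor updated by the optimizer."""

    __slots__ = ("name",)

    def __init__(self, data, name: str):
        super().__init__(data)
        self._parents = ()
        self._backward = None
        self.name = name


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitive operations ---------------------------------------------------

def add(a, b) -> Tensor:
    at, bt = isinstance(a, Tensor), isinstance(b, Tensor)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, (a, b))

    def backward(g):
        if at:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if bt:
            b._accumulate(_unbroadcast(g, b.data.shape))
    out._backward = backward
    return out


def sub(a, b) -> Tensor:
    at, bt = isinstance(a, Tensor), isinstance(b, Tensor)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data - b.data, (a, b))

    def backward(g):
        if at:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if bt:
            b._accumulate(_unbroadcast(-g, b.data.shape))
    out._backward = backward
    return out


def scale(a: Tensor, s: float) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data * s, (a,))
    out._backward = lambda g: a._accumulate(g * s)
    return out


def _unbroadcast(g, shape):
    """Sum g down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def matmul(a, b) -> Tensor:
    """a @ b; either operand may be a constant ndarray (e.g. a forward
    matrix), in which case no gradient is accumulated for it."""
    at, bt = isinstance(a, Tensor), isinstance(b, Tensor)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g):
        if at:
            a._accumulate(g @ b.data.T)
        if bt:
            b._accumulate(a.data.T @ g)
    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), (a,))
    out._backward = lambda g: a._accumulate(g * mask)
    return out


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    a = _wrap(a)
    neg = alpha * np.expm1(np.minimum(a.data, 0.0))
    out = Tensor(np.where(a.data > 0, a.data, neg), (a,))

    def backward(g):
        a._accumulate(g * np.where(a.data > 0, 1.0, neg + alpha))
    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), (a,))
    out._backward = lambda g: a._accumulate(g.reshape(a.data.shape))
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two (B, C, H, W) tensors along the channel axis."""
    a, b = _wrap(a), _wrap(b)
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), (a, b))

    def backward(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])
    out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Same-padding 2D convolution (cross-correlation), square odd kernel.

    x: (B, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,) or None.
    """
    x, w = _wrap(x), _wrap(w)
    B, Cin, H, W = x.data.shape
    Cout, Cin_w, k, _ = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,Cin,H,W,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, Cin * k * k)
    wmat = w.data.reshape(Cout, Cin * k * k)
    out_mat = cols @ wmat.T
    if b is not None:
        out_mat = out_mat + b.data
    out = Tensor(out_mat.reshape(B, H, W, Cout).transpose(0, 3, 1, 2),
                 (x, w) if b is None else (x, w, b))

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * H * W, Cout)
        w._accumulate((gmat.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(gmat.sum(axis=0))
        dcols = (gmat @ wmat).reshape(B, H, W, Cin, k, k)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        x._accumulate(dxp[:, :, p:p + H, p:p + W])
    out._backward = backward
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """2x upsampling transposed convolution, kernel 2, stride 2.

    x: (B, Cin, H, W); w: (Cin, Cout, 2, 2); output (B, Cout, 2H, 2W).
    """
    x, w = _wrap(x), _wrap(w)
    B, Cin, H, W = x.data.shape
    Cout = w.data.shape[1]
    t = np.einsum("bcij,copq->boipjq", x.data, w.data, optimize=True)
    out_data = t.reshape(B, Cout, 2 * H, 2 * W)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    out = Tensor(out_data, (x, w) if b is None else (x, w, b))

    def backward(g):
        g6 = g.reshape(B, Cout, H, 2, W, 2)
        w._accumulate(np.einsum("bcij,boipjq->copq", x.data, g6,
                                optimize=True))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        x._accumulate(np.einsum("boipjq,copq->bcij", g6, w.data,
                                optimize=True))
    out._backward = backward
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (H, W must be even)."""
    x = _wrap(x)
    B, C, H, W = x.data.shape
    v = x.data.reshape(B, C, H // 2, 2, W // 2, 2) \
        .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    idx = v.argmax(axis=-1)
    out = Tensor(np.take_along_axis(v, idx[..., None], axis=-1)[..., 0],
                 (x,))

    def backward(g):
        dv = np.zeros_like(v)
        np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
        dx = dv.reshape(B, C, H // 2, W // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        x._accumulate(dx)
    out._backward = backward
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error over all elements."""
    pred = _wrap(pred)
    diff = pred.data - np.asarray(target, dtype=pred.data.dtype)
    out = Tensor(np.mean(diff * diff), (pred,))
    out._backward = lambda g: pred._accumulate(
        g * 2.0 * diff / diff.size)
    return out


# -- layers -----------------------------------------------------------------

def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Fan-in-scaled normal initialization."""
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Module:
    """Base class: children and parameters are discovered by attribute."""

    def parameters(self) -> list[Parameter]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = {p.name: p for p in self.parameters()}
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, value in state.items():
            if params[name].data.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            params[name].data = np.asarray(value, float).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str):
        self.weight = Parameter(he_init(rng, (n_out, n_in), n_in),
                                f"{name}.weight")
        self.bias = Parameter(np.zeros(n_out), f"{name}.bias")

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, _transpose_param(self.weight)), self.bias)


def _transpose_param(p: Parameter) -> Tensor:
    out = Tensor(p.data.T, (p,))
    out._backward = lambda g: p._accumulate(g.T)
    return out


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, name: str,
                 bias: bool = True, zero_init: bool = False):
        fan_in = c_in * k * k
        w = np.zeros((c_out, c_in, k, k)) if zero_init else \
            he_init(rng, (c_out, c_in, k, k), fan_in)
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(c_out), f"{name}.bias") if bias \
            else None

    def __call__(self, x: Tensor) -> Tensor:
        b = None
        if self.bias is not None:
            bt = Tensor(self.bias.data, (self.bias,))
            bt._backward = self.bias._accumulate
            b = bt
        return conv2d(x, self.weight, b)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str):
        self.weight = Parameter(
            he_init(rng, (c_in, c_out, 2, 2), c_in * 4), f"{name}.weight")
        self.bias = Parameter(np.zeros(c_out), f"{name}.bias")

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias)


class Adam(Module):
    """Adaptive-moments optimizer with optional L1 penalty and freezing."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 l1_weight: float = 0.0,
                 frozen: set[str] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l1_weight = l1_weight
        self.frozen = frozen or set()
        self.t = 0
        self._m = {p.name: np.zeros_like(p.data) for p in params}
        self._v = {p.name: np.zeros_like(p.data) for p in params}

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p in self.params:
            if p.name in self.frozen or p.grad is None:
                continue
            g = p.grad
            if self.l1_weight > 0:
                g = g + self.l1_weight * np.sign(p.data)
            m, v = self._m[p.name], self._v[p.name]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            denom = np.sqrt(v / bc2)
            denom += self.eps
            np.divide(m, denom, out=denom)
            denom *= self.lr / bc1
            p.data -= denom
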