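"""A minimal reverse-mode autodiff engine on numpy arrays.

Implements exactly the operations the localization networks need: strided
2-D convolution (via im2col/col2im), nearest-neighbour upsampling, channel
concatenation, elementwise nonlinearities, dropout, mean/abs reductions and
a numerically stable binary cross-entropy.  Tensors are float32; gradients
are accumulated through a topologically sorted backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "upsample_nearest",
    "concat_channels",
    "leaky_relu",
    "relu",
    "sigmoid",
    "softplus",
    "dropout",
    "mean_abs",
    "bce",
    "add",
    "scale",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: np.ndarray, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        topo: list[Tensor] = []
        visited: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in visited:
                return
            visited.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, Ho, Wo, C*k*k) patch matrix."""
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    n, c, ho, wo, _, _ = view.shape
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW x (K, C, k, k) -> NKH'W'."""
    n, c, h, wd = x.shape
    kk, cc, k, _ = w.shape
    assert cc == c, f"channel mismatch: {cc} vs {c}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = _im2col(xp, k, stride)  # (N, Ho, Wo, C*k*k)
    ho, wo = cols.shape[1], cols.shape[2]
    wmat = w.data.reshape(kk, c * k * k)
    out = cols.reshape(-1, c * k * k) @ wmat.T  # (N*Ho*Wo, K)
    if b is not None:
        out = out + b.data
    out = out.reshape(n, ho, wo, kk).transpose(0, 3, 1, 2)

    def backward(g: np.ndarray) -> None:
        gm = g.transpose(0, 2, 3, 1).reshape(-1, kk)  # (N*Ho*Wo, K)
        if w.requires_grad:
            gw = gm.T @ cols.reshape(-1, c * k * k)
            w._accumulate(gw.reshape(kk, c, k, k))
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if x.requires_grad or x._parents:
            gcols = (gm @ wmat).reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
            hp, wp = xp.shape[2], xp.shape[3]
            gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i : i + stride * ho : stride,
                        j : j + stride * wo : stride] += gcols[:, :, :, :, i, j]
            gx = gxp[:, :, pad : hp - pad, pad : wp - pad] if pad else gxp
            x._accumulate(gx)

    return _make(out, (x, w) if b is None else (x, w, b), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def backward(g: np.ndarray) -> None:
        n, c, h, w = x.shape
        gr = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accumulate(gr)

    return _make(out, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    out = np.concatenate([a.data, b.data], axis=1)
    ca = a.shape[1]

    def backward(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(g[:, :ca])
        if b.requires_grad or b._parents:
            b._accumulate(g[:, ca:])

    return _make(out, (a, b), backward)


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, alpha * x.data)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * np.where(mask, 1.0, alpha).astype(np.float32))

    return _make(out, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return _make(out, (x,), backward)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), a smooth non-negative activation.

    Unlike a ReLU its gradient (the logistic sigmoid) never vanishes, which
    matters for sparse-target regression: the background gradient cannot
    permanently kill the output unit.
    """
    out = np.log1p(np.exp(-np.abs(x.data))) + np.maximum(x.data, 0.0)

    def backward(g: np.ndarray) -> None:
        sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30, 30)))
        x._accumulate((g * sig).astype(np.float32))

    return _make(out.astype(np.float32), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30, 30)))

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * out * (1.0 - out))

    return _make(out, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            active: bool = True) -> Tensor:
    if not active or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    out = x.data * mask

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return _make(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(g)
        if b.requires_grad or b._parents:
            b._accumulate(g)

    return _make(out, (a, b), backward)


def scale(x: Tensor, s: float) -> Tensor:
    out = x.data * s

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * s)

    return _make(out, (x,), backward)


def mean_abs(x: Tensor) -> Tensor:
    """mean(|x|) as a scalar tensor."""
    out = np.array(np.mean(np.abs(x.data)), dtype=np.float32)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * np.sign(x.data).astype(np.float32) / x.data.size)

    return _make(out, (x,), backward)


def mean_abs_diff(a: Tensor, b: Tensor) -> Tensor:
    """mean(|a - b|) as a scalar tensor."""
    diff = a.data - b.data
    out = np.array(np.mean(np.abs(diff)), dtype=np.float32)

    def backward(g: np.ndarray) -> None:
        s = g * np.sign(diff).astype(np.float32) / diff.size
        if a.requires_grad or a._parents:
            a._accumulate(s)
        if b.requires_grad or b._parents:
            b._accumulate(-s)

    return _make(out, (a, b), backward)


def bce(scores: Tensor, target: float, eps: float = 1e-6) -> Tensor:
    """Binary cross-entropy of probability scores against a constant label."""
    p = np.clip(scores.data, eps, 1.0 - eps)
    out = np.array(
        -np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)),
        dtype=np.float32,
    )

    def backward(g: np.ndarray) -> None:
        grad = (p - target) / (p * (1.0 - p)) / p.size
        inside = (scores.data > eps) & (scores.data < 1.0 - eps)
        scores._accumulate(g * (grad * inside).astype(np.float32))

    return _make(out, (scores,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.25, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
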