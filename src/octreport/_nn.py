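"""Minimal reverse-mode automatic differentiation on numpy arrays.

The recognition models in this package are small enough that a compact,
vectorized tape-based autodiff (a few hundred lines) covers everything they
need: broadcast arithmetic, matmul, the usual activations, axis softmax,
3x3 same-padding convolution via strided windows, 2x2 max-pooling, and a fused
softmax cross-entropy.  Gradients flow through Python-level loops over
time-steps, which is how the recurrent layers are expressed.

Everything computes in float32.  Only ``Tensor`` objects created as
parameters (``requires_grad=True``) accumulate gradients; constants are
wrapped on the fly and contribute no tape nodes.
"""

from __future__ import annotations

import json
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "softmax_cross_entropy",
    "AdaDelta",
    "clip_global_norm",
    "save_params",
    "load_params",
]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- activations -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        def backward(g):
            self._accum(g * mask)
        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -30, 30)))
        def backward(g):
            self._accum(g * out * (1.0 - out))
        return self._make(out, (self,), backward)

    def tanh(self):
        out = np.tanh(self.data)
        def backward(g):
            self._accum(g * (1.0 - out * out))
        return self._make(out, (self,), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        def backward(g):
            self._accum(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        def backward(g):
            self._accum(g.transpose(*inv))
        return self._make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, idx):
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int)) for p in parts)

        def backward(g):
            full = np.zeros_like(self.data)
            if basic:  # basic-index views are disjoint: assignment suffices
                full[idx] = g
            else:
                np.add.at(full, idx, g)
            self._accum(full)
        return self._make(self.data[idx], (self,), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)
        def backward(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            self._accum((g - dot) * out)
        return self._make(out, (self,), backward)

    # -- image ops ---------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """3x3 same-padding, stride-1 convolution.

        self: (N,C,H,W); weight: (OC, C*9); bias: (OC,).
        """
        N, C, H, W = self.data.shape
        OC = weight.data.shape[0]
        xp = np.pad(self.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
        s = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, (N, C, 3, 3, H, W), (s[0], s[1], s[2], s[3], s[2], s[3]))
        cols = np.ascontiguousarray(win).reshape(N, C * 9, H * W)
        out = (weight.data[None] @ cols).reshape(N, OC, H, W) \
            + bias.data[None, :, None, None]

        def backward(g):
            gy = g.reshape(N, OC, H * W)
            if weight.requires_grad:
                gw = np.einsum("noh,nch->oc", gy, cols, optimize=True)
                weight._accum(gw)
            if bias.requires_grad:
                bias._accum(gy.sum(axis=(0, 2)))
            if self.requires_grad:
                gcols = (weight.data.T[None] @ gy).reshape(N, C, 3, 3, H, W)
                gxp = np.zeros_like(xp)
                for i in range(3):
                    for j in range(3):
                        gxp[:, :, i:i + H, j:j + W] += gcols[:, :, i, j]
                self._accum(gxp[:, :, 1:1 + H, 1:1 + W])

        return self._make(out, (self, weight, bias), backward)

    def maxpool(self, kh: int = 2, kw: int = 2) -> "Tensor":
        """kh x kw max pooling; H % kh == 0 and W % kw == 0."""
        N, C, H, W = self.data.shape
        Ho, Wo = H // kh, W // kw
        xr = self.data.reshape(N, C, Ho, kh, Wo, kw).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(N, C, Ho, Wo, kh * kw)
        arg = xr.argmax(axis=4)
        out = np.take_along_axis(xr, arg[..., None], axis=4)[..., 0]

        def backward(g):
            gr = np.zeros((N, C, Ho, Wo, kh * kw), dtype=np.float32)
            np.put_along_axis(gr, arg[..., None], g[..., None], axis=4)
            gx = gr.reshape(N, C, Ho, Wo, kh, kw).transpose(0, 1, 2, 4, 3, 5) \
                .reshape(N, C, H, W)
            self._accum(gx)

        return self._make(out, (self,), backward)

    def maxpool2(self) -> "Tensor":
        return self.maxpool(2, 2)

    # -- autograd core -----------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    req = any(t.requires_grad for t in tensors)
    if not req:
        return Tensor(out_data)
    return Tensor(out_data, requires_grad=True, parents=tuple(tensors),
                  backward=backward)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          weights: np.ndarray) -> Tensor:
    """Mean weighted cross-entropy over rows of (B,V) logits.

    `targets` are integer class ids, `weights` per-row weights (0 masks a row
    out).  Returns a scalar tensor; normalizes by sum(weights).
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    B = logits.data.shape[0]
    wsum = max(float(weights.sum()), 1e-8)
    nll = -np.log(np.maximum(p[np.arange(B), targets], 1e-12))
    loss = float((nll * weights).sum() / wsum)

    def backward(g):
        dp = p.copy()
        dp[np.arange(B), targets] -= 1.0
        dp *= (weights / wsum)[:, None]
        logits._accum(g * dp)

    if not logits.requires_grad:
        return Tensor(loss)
    return Tensor(loss, requires_grad=True, parents=(logits,), backward=backward)


class AdaDelta:
    """AdaDelta optimizer (Zeiler 2012): learning rate 1, decay rho, eps."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1.0,
                 rho: float = 0.95, eps: float = 1e-6):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._eg2 = [np.zeros_like(p.data) for p in self.params]
        self._ed2 = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, eg2, ed2 in zip(self.params, self._eg2, self._ed2):
            if p.grad is None:
                continue
            g = p.grad
            eg2 *= self.rho
            eg2 += (1.0 - self.rho) * g * g
            delta = -np.sqrt((ed2 + self.eps) / (eg2 + self.eps)) * g
            ed2 *= self.rho
            ed2 += (1.0 - self.rho) * delta * delta
            p.data += self.lr * delta

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_global_norm(params: Sequence[Tensor], max_norm: float = 5.0):
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


def save_params(path, named_params: dict[str, Tensor], meta: dict):
    arrays = {k: v.data for k, v in named_params.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_params(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode("utf-8"))
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    return arrays, meta
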