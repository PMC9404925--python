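"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations needed by the 1D W-Net and its composite
loss: elementwise arithmetic with broadcasting, reductions (sum, mean, max),
abs/sqrt/tanh/LeakyReLU, channel concatenation, same-padded 1D convolution
(im2col + BLAS matmul), average pooling / nearest-neighbour upsampling by 2,
and batch normalization with running statistics.  All tensors are float32;
gradients flow through a topologically sorted tape.

Convolution gradients avoid a scatter (col2im): the input gradient is itself
a same-padded correlation of the output gradient with the kernel flipped
along its tap axis and transposed in its channel axes, which holds for odd
kernel sizes with symmetric padding.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # intermediate activations: release the gradient buffer as
                # soon as it has been propagated (leaf parameters keep theirs)
                node.grad = None

    # ---- elementwise arithmetic -------------------------------------------

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        need = self.requires_grad or other.requires_grad

        def backward(g: np.ndarray) -> None:
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(bwd_self(g), self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(bwd_other(g), other.data.shape))

        return Tensor(out_data, need, (self, other), backward)

    def __add__(self, other) -> "Tensor":
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other) -> "Tensor":
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return other.__sub__(self)

    def __mul__(self, other) -> "Tensor":
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(other_t, np.multiply,
                            lambda g: g * other_t.data, lambda g: g * self.data)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(other_t, np.divide,
                            lambda g: g / other_t.data,
                            lambda g: -g * self.data / (other_t.data ** 2))

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,),
                     None)
        out._backward = lambda g: self._accumulate(-g)
        return out

    # ---- reductions --------------------------------------------------------

    def sum(self, axes: tuple[int, ...] | None = None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axes, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            gg = g
            if not keepdims and axes is not None:
                gg = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(gg, self.data.shape))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def mean(self, axes: tuple[int, ...] | None = None, keepdims: bool = False) -> "Tensor":
        if axes is None:
            count = self.data.size
        else:
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axes, keepdims) * (1.0 / count)

    def max(self, axes: tuple[int, ...]) -> "Tensor":
        out_data = self.data.max(axis=axes, keepdims=True)
        mask = (self.data == out_data)
        # distribute over ties so the gradient sums to 1 per reduced group
        mask = mask / mask.sum(axis=axes, keepdims=True)
        squeezed = out_data.squeeze(axis=axes)

        def backward(g: np.ndarray) -> None:
            self._accumulate(np.expand_dims(g, axes) * mask)

        return Tensor(squeezed, self.requires_grad, (self,), backward)

    # ---- elementwise functions --------------------------------------------

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)
        sign = np.sign(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * sign)

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def leaky_relu(self, slope: float = 0.1) -> "Tensor":
        factor = np.where(self.data > 0, np.float32(1.0), np.float32(slope))
        out_data = self.data * factor

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * factor)

        return Tensor(out_data, self.requires_grad, (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (channel axis for (N, C, L) activations)."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    need = any(t.requires_grad or t._parents for t in tensors)
    return Tensor(out_data, need, tuple(tensors), backward)


def _im2col(x: np.ndarray, K: int) -> np.ndarray:
    """(N, L, C) -> (N*L, K*C) patch matrix for a same-padded width-K window."""
    N, L, C = x.shape
    p = K // 2
    xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
    s0, s1, s2 = xp.strides
    win = as_strided(xp, (N, L, K, C), (s0, s1, s1, s2))
    return win.reshape(N * L, K * C)  # copies once into GEMM layout


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1D convolution: x (N, L, C), w (K, C, F), b (F,) -> (N, L, F).

    Channels-last layout keeps the forward pass a single im2col copy plus one
    GEMM; the input gradient is a second GEMM against the tap-flipped,
    channel-swapped kernel.  The patch matrix is rebuilt in the backward pass
    rather than cached, trading ~10% extra work for a flat memory profile.
    """
    N, L, C = x.data.shape
    K, Cw, F = w.data.shape
    if Cw != C:
        raise ValueError(f"conv1d channel mismatch: input has {C}, kernel expects {Cw}")
    if K % 2 != 1:
        raise ValueError("kernel size must be odd for symmetric same padding")
    cols = _im2col(x.data, K)
    out_data = (cols @ w.data.reshape(K * C, F)) + b.data
    out_data = out_data.reshape(N, L, F)
    del cols

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(N * L, F)
        cols = _im2col(x.data, K)
        w._accumulate((cols.T @ g2).reshape(K, C, F))
        del cols
        b._accumulate(g2.sum(axis=0))
        if x.requires_grad or x._parents:
            # dL/dx = same-padded correlation of g with w flipped along taps
            # and transposed in (C, F)
            w_t = w.data[::-1].transpose(0, 2, 1).reshape(K * F, C)
            gcols = _im2col(g, K)
            x._accumulate((gcols @ w_t).reshape(N, L, C))

    return Tensor(out_data, True, (x, w, b), backward)


def avgpool2(x: Tensor) -> Tensor:
    """Average pooling by 2 along the time axis of (N, L, C); L must be even."""
    N, L, C = x.data.shape
    if L % 2 != 0:
        raise ValueError("length must be even for pooling by 2")
    out_data = x.data.reshape(N, L // 2, 2, C).mean(axis=2)

    def backward(g: np.ndarray) -> None:
        x._accumulate(np.repeat(g, 2, axis=1) * 0.5)

    return Tensor(out_data, x.requires_grad, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by 2 along the time axis of (N, L, C)."""
    N, L, C = x.data.shape
    out_data = np.repeat(x.data, 2, axis=1)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g.reshape(N, L, 2, C).sum(axis=2))

    return Tensor(out_data, x.requires_grad, (x,), backward)


class BatchNorm1d:
    """Per-channel batch normalization over (N, L, C) with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        if training:
            mu = x.data.mean(axis=(0, 1))
            var = x.data.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
        xhat = (x.data - mu) * inv_std
        out_data = gamma.data * xhat + beta.data

        def backward(g: np.ndarray) -> None:
            gamma._accumulate((g * xhat).sum(axis=(0, 1)))
            beta._accumulate(g.sum(axis=(0, 1)))
            if not (x.requires_grad or x._parents):
                return
            gs = gamma.data * inv_std
            if training:
                mean_g = g.mean(axis=(0, 1), keepdims=True)
                mean_gx = (g * xhat).mean(axis=(0, 1), keepdims=True)
                x._accumulate(gs * (g - mean_g - xhat * mean_gx))
            else:
                x._accumulate(gs * g)

        return Tensor(out_data, True, (x, gamma, beta), backward)


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= np.float32(self.lr) * mhat / (np.sqrt(vhat) + self.eps)
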