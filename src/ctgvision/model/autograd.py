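"""Minimal reverse-mode automatic differentiation on numpy arrays.

The classifier in this package is small enough to train on a CPU, so the
network is built on this self-contained tape-based autograd rather than an
external deep-learning framework.  A :class:`Tensor` wraps a float64 ndarray;
operations record their inputs and a backward closure, and :meth:`Tensor.backward`
propagates gradients through the reverse topological order of the tape.

Only the operations the network needs are provided: broadcast arithmetic,
matmul, dense/depthwise 2-D convolution (im2col based), batch normalization,
reductions (sum/mean/max), elementwise activations, reshape/concat, dropout,
and a fused softmax cross-entropy.  Every operator is validated against
finite-difference and naive-loop oracles in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray node on the autograd tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += -g
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / other.data**2, other.shape)
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g
        out._backward = bw
        return out

    # -- shaping -----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(self.shape)
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.shape)
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self.grad += np.broadcast_to(gg, self.shape)
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = False):
        """Maximum over axes; ties share the gradient equally."""
        data = self.data.max(axis=axis, keepdims=True)
        out_data = data if keepdims else np.squeeze(data, axis=axis)
        out = Tensor(out_data, _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            tie = (self.data == data).astype(np.float64)
            tie /= tie.sum(axis=axis, keepdims=True)
            self.grad += np.broadcast_to(gg, self.shape) * tie
        out._backward = bw
        return out


# -- elementwise activations ----------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x.grad += g * (x.data > 0)
    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x.grad += g * s * (1.0 - s)
    out._backward = bw
    return out


def silu(x: Tensor) -> Tensor:
    """Sigmoid Linear Unit, x * sigmoid(x)."""
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(x.data * s, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x.grad += g * (s + x.data * s * (1.0 - s))
    out._backward = bw
    return out


def concat(tensors: list, axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.grad += piece
    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * keep, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x.grad += g * keep
    out._backward = bw
    return out


# -- convolution -----------------------------------------------------------

def _sliding_windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Ho, Wo, k, k) view of a padded input."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def _col2im(gwin: np.ndarray, padded_shape: tuple, k: int, stride: int,
            pad: int, out_shape: tuple) -> np.ndarray:
    """Scatter-add window gradients back to the input layout."""
    gxp = np.zeros(padded_shape)
    N, C, Ho, Wo, _, _ = gwin.shape
    for i in range(k):
        for j in range(k):
            gxp[:, :, i:i + stride * Ho:stride,
                j:j + stride * Wo:stride] += gwin[:, :, :, :, i, j]
    if pad:
        gxp = gxp[:, :, pad:pad + out_shape[2], pad:pad + out_shape[3]]
    return gxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2-D convolution (cross-correlation), NCHW layout."""
    N, C, H, W = x.shape
    Cout, Cin, k, k2 = weight.shape
    if k != k2:
        raise ValueError("square kernels only")
    if Cin != C:
        raise ValueError("channel mismatch")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    win = _sliding_windows(xp, k, stride)           # N,C,Ho,Wo,k,k
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
    wmat = weight.data.reshape(Cout, -1)
    out_data = cols @ wmat.T
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, _parents=parents)

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Cout)
        if weight.requires_grad:
            weight.grad += (gmat.T @ cols).reshape(weight.shape)
        if bias is not None and bias.requires_grad:
            bias.grad += gmat.sum(axis=0)
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(N, Ho, Wo, C, k, k)
            gwin = gcols.transpose(0, 3, 1, 2, 4, 5)
            x.grad += _col2im(gwin, xp.shape, k, stride, padding, x.shape)
    out._backward = bw
    return out


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise 2-D convolution: one k x k filter per input channel.

    ``weight`` has shape (C, k, k); channel c of the output convolves only
    channel c of the input.
    """
    N, C, H, W = x.shape
    Cw, k, k2 = weight.shape
    if k != k2:
        raise ValueError("square kernels only")
    if Cw != C:
        raise ValueError("channel mismatch")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    win = _sliding_windows(xp, k, stride)           # N,C,Ho,Wo,k,k
    out_data = np.einsum("nchwij,cij->nchw", win, weight.data)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, _parents=parents)

    def bw(g):
        if weight.requires_grad:
            weight.grad += np.einsum("nchw,nchwij->cij", g, win)
        if bias is not None and bias.requires_grad:
            bias.grad += g.sum(axis=(0, 2, 3))
        if x.requires_grad:
            gwin = g[:, :, :, :, None, None] * weight.data[None, :, None, None, :, :]
            x.grad += _col2im(gwin, xp.shape, k, stride, padding, x.shape)
    out._backward = bw
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel, NCHW layout.

    In training mode batch statistics are used and the running estimates are
    updated in place; in eval mode the running estimates are used.
    """
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size / x.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased estimate for the running variance, biased for the batch
        running_var += momentum * var * (m / max(m - 1.0, 1.0))
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat \
        + beta.data[None, :, None, None]
    out = Tensor(out_data, _parents=(x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma.grad += (g * xhat).sum(axis=axes)
        if beta.requires_grad:
            beta.grad += g.sum(axis=axes)
        if x.requires_grad:
            gscaled = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.size / x.shape[1]
                gm = gscaled.mean(axis=axes)
                gxh = (gscaled * xhat).mean(axis=axes)
                x.grad += inv[None, :, None, None] * (
                    gscaled - gm[None, :, None, None]
                    - xhat * gxh[None, :, None, None])
            else:
                x.grad += gscaled * inv[None, :, None, None]
    out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against (N, K) logits."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(labels)
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(loss, _parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits.grad += g * p / n
    out._backward = bw
    return out
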