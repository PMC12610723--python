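"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is a small tape-based engine in the style of micrograd, generalised to
ndarrays: every ``Tensor`` wraps a float64 array, records its parents, and a
closure that scatters the upstream gradient back to them.  It provides exactly
the operations the EEG network needs — broadcasting arithmetic, matmul, the
usual pointwise nonlinearities, reductions, shape surgery, valid/same 1-D
convolution and max-pooling — nothing more.

Gradient checks for every op live in the test suite (central finite
differences on random small inputs).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (default seed: ones)."""
        # iterative topological sort to avoid recursion limits on long tapes
        topo: list[Tensor] = []
        scheduled = set()
        stack_ = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if not node.requires_grad:
                continue
            if processed:
                topo.append(node)
            elif id(node) not in scheduled:
                scheduled.add(id(node))
                stack_.append((node, True))
                for p in node._prev:
                    if id(p) not in scheduled and p.requires_grad:
                        stack_.append((p, False))

        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        assert isinstance(p, (int, float)), "only scalar exponents"
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._result(out_data, (self, other), backward)

    # ------------------------------------------------------------- pointwise

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._result(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._result(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return self._result(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._result(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._result(out_data, (self,), backward)

    # ------------------------------------------------------------- reductions

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def log_softmax(self, axis: int = -1):
        """Numerically stable log-softmax along ``axis``."""
        m = self.data.max(axis=axis, keepdims=True)  # constant shift
        shifted = self - Tensor(m)
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    # ---------------------------------------------------------- shape surgery

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old_shape))

        return self._result(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._result(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        idx_tuple = idx if isinstance(idx, tuple) else (idx,)
        fancy = any(isinstance(i, (np.ndarray, list)) for i in idx_tuple)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if fancy:  # may contain duplicate indices
                    np.add.at(full, idx, g)
                else:      # basic indexing: no duplicates possible
                    full[idx] += g
                self._accum(full)

        return self._result(out_data, (self,), backward)

    # ------------------------------------------------------------ conv / pool

    def conv1d(self, weight: "Tensor", bias: "Tensor", stride: int = 1,
               padding: int = 0):
        """1-D convolution.  self: (B, Cin, L); weight: (Cout, Cin, K)."""
        x = self.data
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        B, Cin, L = x.shape
        Cout, _, K = weight.data.shape
        T = (L - K) // stride + 1
        # im2col windows: (B, Cin, T, K)
        win = np.lib.stride_tricks.sliding_window_view(x, K, axis=2)[:, :, ::stride, :]
        # contract over (Cin, K) via BLAS: (B, T, Cout) -> (B, Cout, T)
        out_data = np.tensordot(win, weight.data, axes=([1, 3], [1, 2]))
        out_data = np.ascontiguousarray(out_data.transpose(0, 2, 1))
        out_data += bias.data[None, :, None]

        def backward(g):
            # g: (B, Cout, T)
            if weight.requires_grad:
                # contract over (B, T): (Cout, Cin, K)
                gw = np.tensordot(g, win, axes=([0, 2], [0, 2]))
                weight._accum(gw)
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if self.requires_grad:
                gx = np.zeros_like(x)
                # scatter over kernel offsets: for offset k, output t maps to
                # input position t*stride + k (strided, hence duplicate-free)
                contrib = np.tensordot(g, weight.data, axes=([1], [0]))  # (B,T,Cin,K)
                contrib = contrib.transpose(0, 2, 3, 1)                  # (B,Cin,K,T)
                for k in range(K):
                    gx[:, :, k:k + T * stride:stride] += contrib[:, :, k, :]
                if padding:
                    gx = gx[:, :, padding:-padding or None]
                self._accum(gx)

        return self._result(out_data, (self, weight, bias), backward)

    def maxpool1d(self, window: int, stride: int):
        """Max pooling over the last axis.  self: (B, C, L)."""
        B, C, L = self.data.shape
        T = (L - window) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(self.data, window, axis=2)[:, :, ::stride, :]
        arg = win.argmax(axis=3)  # (B, C, T)
        out_data = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            b_idx, c_idx, t_idx = np.indices(arg.shape)
            pos = t_idx * stride + arg
            np.add.at(gx, (b_idx, c_idx, pos), g)
            self._accum(gx)

        return self._result(out_data, (self,), backward)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(p)

    return Tensor._result(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._coerce(t)
        shape = list(t.data.shape)
        shape.insert(axis if axis >= 0 else len(shape) + 1 + axis, 1)
        expanded.append(t.reshape(shape))
    return concatenate(expanded, axis=axis)
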