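"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core under the temporal-convolutional autoencoder and the
Transformer link predictor.  It implements exactly the operations those models
need (dense/batched matmul, dilated causal 1-D convolution, elementwise
nonlinearities, reductions, row gathering/concatenation) as a tape of
``Tensor`` nodes; ``Tensor.backward`` walks the tape in reverse topological
order accumulating gradients.  Gradients of every op are checked against
central finite differences in the test suite.

All computation is float64 and single-threaded NumPy, which makes seeded
training bit-reproducible on one machine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._node(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            return (g * e * self.data ** (e - 1.0),)

        return Tensor._node(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 or b.ndim == 1:  # not used by the models; keep simple
                raise NotImplementedError("matmul backward requires ndim >= 2")
            ga = g @ b.swapaxes(-1, -2)
            gb = a.swapaxes(-1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._node(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._node(np.where(mask, self.data, 0.0), (self,), backward)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            return (g * out * (1.0 - out),)

        return Tensor._node(out, (self,), backward)

    def tanh(self):
        out = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out**2),)

        return Tensor._node(out, (self,), backward)

    def exp(self):
        out = np.exp(self.data)

        def backward(g):
            return (g * out,)

        return Tensor._node(out, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return Tensor._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        out = np.sqrt(self.data)

        def backward(g):
            return (g * 0.5 / out,)

        return Tensor._node(out, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the interval."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            return (g * inside,)

        return Tensor._node(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions & shape ops -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g):
            return (g.reshape(self.shape),)

        return Tensor._node(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            return (g.swapaxes(a, b),)

        return Tensor._node(self.data.swapaxes(a, b), (self,), backward)

    def gather_rows(self, idx):
        """Select rows ``idx`` along axis 0; backward scatter-adds."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g):
            out = np.zeros(self.shape)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._node(self.data[idx], (self,), backward)

    # -- composite ops ---------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0):
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        return Tensor._node(
            np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
        )

    # -- dilated causal convolution ---------------------------------------------
    def conv1d_causal(self, weight: "Tensor", bias: "Tensor", dilation: int = 1):
        """Causal dilated 1-D convolution with implicit chomp.

        Input ``(B, C_in, L)``, weight ``(C_out, C_in, K)``, bias ``(C_out,)``.
        The input is left-padded by ``(K - 1) * dilation`` zeros so the output
        has length L and position ``t`` depends only on inputs at ``<= t``
        (pad-then-chomp in one step).
        """
        weight = Tensor._lift(weight)
        bias = Tensor._lift(bias)
        x, w = self.data, weight.data
        if x.ndim != 3 or w.ndim != 3:
            raise ValueError("conv1d_causal expects (B, C_in, L) input and (C_out, C_in, K) weight")
        B, Cin, L = x.shape
        Cout, Cin_w, K = w.shape
        if Cin != Cin_w:
            raise ValueError(f"channel mismatch: input has {Cin}, weight expects {Cin_w}")
        pad = (K - 1) * dilation
        if pad:
            xp = np.empty((B, Cin, L + pad))
            xp[:, :, :pad] = 0.0
            xp[:, :, pad:] = x
        else:
            xp = x
        # stack the K dilated taps into one (B, K*Cin, L) operand so the whole
        # convolution is a single batched GEMM
        sb, si, sl = xp.strides
        taps = np.lib.stride_tricks.as_strided(
            xp, shape=(B, K, Cin, L), strides=(sb, dilation * sl, si, sl)
        ).reshape(B, K * Cin, L)
        wflat = w.transpose(0, 2, 1).reshape(Cout, K * Cin)  # wflat[o, k*Cin+i]
        out = wflat @ taps + bias.data[None, :, None]

        def backward(g):
            gwflat = (g @ taps.swapaxes(1, 2)).sum(axis=0)
            gw = gwflat.reshape(Cout, K, Cin).transpose(0, 2, 1)
            gtaps = wflat.T @ g  # (B, K*Cin, L)
            gxp = np.zeros((B, Cin, L + pad))
            for k in range(K):
                gxp[:, :, k * dilation : k * dilation + L] += gtaps[
                    :, k * Cin : (k + 1) * Cin, :
                ]
            gx = gxp[:, :, pad:] if pad else gxp
            gb = g.sum(axis=(0, 2))
            return gx, gw, gb

        return Tensor._node(out, (self, weight, bias), backward)

    # -- backward pass -----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.asarray(g, dtype=np.float64).copy()
                else:
                    parent.grad += g


class Parameter(Tensor):
    """A trainable tensor (``requires_grad=True`` by construction)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
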