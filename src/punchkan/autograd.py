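"""Minimal reverse-mode tensor autodiff on numpy arrays.

Supports exactly the operations the regression models need: broadcasting
arithmetic, batched matmul, tanh/sigmoid, axis reductions, last-axis slicing,
depthwise 1-D convolution and a centered shrinking-window moving average.
Gradients are accumulated by topological traversal; correctness is pinned by
central-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "depthwise_conv1d", "moving_average", "slice_last", "select_time"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def _as_tensor(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._as_tensor(other))

    def __rsub__(self, other):
        return self._as_tensor(other) + (-self)

    def __mul__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                raise NotImplementedError("1-D left operand in matmul")
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b
                gb = np.tensordot(g, a, axes=(tuple(range(g.ndim)), tuple(range(g.ndim))))
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- nonlinearities -------------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * (1.0 - y**2),)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: (g * np.sign(self.data),)
        return out

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if not p.requires_grad or g is None:
                    continue
                p.grad = g if p.grad is None else p.grad + g


# -- structured operations ----------------------------------------------------

def slice_last(t: Tensor, start: int, stop: int) -> Tensor:
    """Slice along the last axis (used to split recurrent gate pre-activations)."""
    out = Tensor(t.data[..., start:stop], _parents=(t,))

    def backward(g):
        full = np.zeros_like(t.data)
        full[..., start:stop] = g
        return (full,)

    out._backward = backward
    return out


def select_time(t: Tensor, i: int) -> Tensor:
    """Select time step i from a (B, T, C) tensor -> (B, C)."""
    out = Tensor(t.data[:, i, :], _parents=(t,))

    def backward(g):
        full = np.zeros_like(t.data)
        full[:, i, :] = g
        return (full,)

    out._backward = backward
    return out


def depthwise_conv1d(x: Tensor, kernels: Tensor) -> Tensor:
    """Per-channel 1-D convolution, same-length output via zero padding.

    x: (B, T, D); kernels: (M, D) — channel d is convolved only with kernel
    column d (group count = D).
    """
    B, T, D = x.data.shape
    M, Dk = kernels.data.shape
    if Dk != D:
        raise ValueError(f"kernel channels {Dk} != data channels {D}")
    if M > T:
        raise ValueError(f"kernel length {M} exceeds trace length {T}")
    left = M // 2
    right = M - 1 - left
    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, M, axis=1)  # (B,T,D,M)
    out = Tensor(np.einsum("btdm,md->btd", win, kernels.data), _parents=(x, kernels))

    def backward(g):
        gk = np.einsum("btdm,btd->md", win, g)
        gxp = np.zeros_like(xp)
        for m in range(M):
            gxp[:, m : m + T, :] += g * kernels.data[m]
        return (gxp[:, left : left + T, :], gk)

    out._backward = backward
    return out


def cheb_layer(z: Tensor, theta: Tensor) -> Tensor:
    """Fused KAN layer: out[..., j] = sum_{i,k} theta[k, i, j] * T_k(tanh z[..., i]).

    theta: (K+1, n_in, n_out). Equivalent to building the Chebyshev recurrence
    from elementwise ops, but with one graph node; the input gradient uses
    dT_k/du = k * U_{k-1}(u) (second-kind Chebyshev recurrence).
    """
    K1, n_in, n_out = theta.data.shape
    K = K1 - 1
    u = np.tanh(z.data)
    N = u.size // n_in
    u2 = u.reshape(N, n_in)
    basis = np.empty((N, K1, n_in))  # (k, i) contiguous for one flat GEMM
    basis[:, 0, :] = 1.0
    if K >= 1:
        basis[:, 1, :] = u2
    for k in range(1, K):
        basis[:, k + 1, :] = 2.0 * u2 * basis[:, k, :] - basis[:, k - 1, :]
    bflat = basis.reshape(N, K1 * n_in)
    tflat = theta.data.reshape(K1 * n_in, n_out)
    out_data = (bflat @ tflat).reshape(z.data.shape[:-1] + (n_out,))
    out = Tensor(out_data, _parents=(z, theta))

    def backward(g):
        g2 = g.reshape(N, n_out)
        gtheta = (bflat.T @ g2).reshape(K1, n_in, n_out)
        # dT_k/du = k * U_{k-1}(u); sum_k k*U_{k-1} * (g @ theta_k^T)
        w = (g2 @ tflat.T).reshape(N, K1, n_in)
        gz = np.zeros_like(u2)
        u_prevprev = None
        u_prev = np.ones_like(u2)  # U_0
        for k in range(1, K1):
            gz += k * u_prev * w[:, k, :]
            u_next = 2.0 * u2 * u_prev if u_prevprev is None else 2.0 * u2 * u_prev - u_prevprev
            u_prevprev, u_prev = u_prev, u_next
        gz *= 1.0 - u2**2  # chain through tanh
        return (gz.reshape(z.data.shape), gtheta)

    out._backward = backward
    return out


def _window_bounds(T: int, half: int):
    idx = np.arange(T)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, T - 1)
    return lo, hi, (hi - lo + 1).astype(np.float64)


def _clipped_window_sum(a: np.ndarray, half: int, axis: int) -> np.ndarray:
    """Sum over a centered window of half-width `half`, clipped at the edges."""
    a = np.moveaxis(a, axis, 0)
    T = a.shape[0]
    lo, hi, _ = _window_bounds(T, half)
    c = np.cumsum(a, axis=0)
    zero = np.zeros_like(c[0])
    csum = np.concatenate([zero[None], c], axis=0)  # csum[i] = sum of a[:i]
    out = csum[hi + 1] - csum[lo]
    return np.moveaxis(out, 0, axis)


def moving_average(x: Tensor, window: int, axis: int = 1) -> Tensor:
    """Centered moving average with shrinking windows at the edges.

    `window` must be odd so the window is symmetric about each sample.
    Linear operator; the backward pass is its transpose.
    """
    if window % 2 != 1:
        raise ValueError("moving_average window must be odd")
    half = window // 2
    T = x.data.shape[axis]
    shape = [1] * x.data.ndim
    shape[axis] = T
    counts = _window_bounds(T, half)[2].reshape(shape)
    out = Tensor(_clipped_window_sum(x.data, half, axis) / counts, _parents=(x,))
    out._backward = lambda g: (_clipped_window_sum(g / counts, half, axis),)
    return out
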