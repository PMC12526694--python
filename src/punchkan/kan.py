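"""Chebyshev-basis Kolmogorov-Arnold network for time-series regression.

Every edge of a KAN layer carries a learnable univariate function
phi(x) = sum_k Theta_k * T_k(tanh x), where T_k(x) = cos(k arccos x) is the
k-th Chebyshev polynomial; node j of the next layer sums the edge responses
of all incoming neurons. The regressor wraps the KAN core the way
multiscale time-series models do:

    per-step linear embedding (C -> D channels)
    -> depthwise convolution (one kernel per embedding channel)
    -> frequency decomposition (moving-average cascade, residuals at
       successively finer scales; components sum exactly to the input)
    -> one KAN stack per component, Chebyshev order increasing from the
       low-frequency to the high-frequency component (default K = 2, 3, 5)
    -> recombination (sum), mean pooling over time, linear head -> scalar.

The plain-numpy functions (`chebyshev_basis`, `edge_response`,
`layer_forward`) are the reference semantics; `ChebyshevKANRegressor` is the
trainable model built on the autograd engine and agrees with them exactly.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .autograd import Tensor, cheb_layer, depthwise_conv1d, moving_average

__all__ = [
    "chebyshev_basis",
    "ChebyshevEdge",
    "edge_response",
    "KANLayer",
    "layer_forward",
    "frequency_decompose",
    "KANConfig",
    "ChebyshevKANRegressor",
]


# ---------------------------------------------------------------------------
# reference (numpy) semantics
# ---------------------------------------------------------------------------

def chebyshev_basis(u, K: int) -> np.ndarray:
    """T_0..T_K at u in [-1, 1] via the stable recurrence T_{k+1} = 2u T_k - T_{k-1}.

    Returns an array of shape ``u.shape + (K+1,)``.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    u = np.asarray(u, dtype=np.float64)
    if np.any(np.abs(u) > 1.0 + 1e-12):
        raise ValueError("basis argument outside [-1, 1]")
    u = np.clip(u, -1.0, 1.0)
    out = np.empty(u.shape + (K + 1,))
    out[..., 0] = 1.0
    if K >= 1:
        out[..., 1] = u
    for k in range(1, K):
        out[..., k + 1] = 2.0 * u * out[..., k] - out[..., k - 1]
    return out


@dataclass(frozen=True)
class ChebyshevEdge:
    """One learnable edge function: coefficients Theta_0..Theta_K."""

    coefficients: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", np.atleast_1d(np.asarray(self.coefficients, dtype=np.float64))
        )
        if self.coefficients.ndim != 1 or self.coefficients.size < 1:
            raise ValueError("coefficients must be a nonempty 1-D array")

    @property
    def order(self) -> int:
        return self.coefficients.size - 1


def edge_response(x, edge: ChebyshevEdge):
    """phi(x) = sum_k Theta_k T_k(tanh x); accepts scalars or arrays."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("edge input must be finite")
    basis = chebyshev_basis(np.tanh(x), edge.order)
    return basis @ edge.coefficients


@dataclass
class KANLayer:
    """A complete n_out x n_in grid of Chebyshev edges sharing one order K.

    ``theta`` has shape (n_out, n_in, K+1).
    """

    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.ndim != 3:
            raise ValueError("theta must have shape (n_out, n_in, K+1)")

    @property
    def n_in(self) -> int:
        return self.theta.shape[1]

    @property
    def n_out(self) -> int:
        return self.theta.shape[0]

    @property
    def order(self) -> int:
        return self.theta.shape[2] - 1

    def edge(self, j: int, i: int) -> ChebyshevEdge:
        return ChebyshevEdge(self.theta[j, i])


def layer_forward(z: np.ndarray, layer: KANLayer) -> np.ndarray:
    """z_{l+1,j} = sum_i phi_{j,i}(z_{l,i}) for a batch of input vectors."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape[-1] != layer.n_in:
        raise ValueError(f"input width {z.shape[-1]} != layer n_in {layer.n_in}")
    basis = chebyshev_basis(np.tanh(z), layer.order)  # (..., n_in, K+1)
    return np.einsum("...ik,jik->...j", basis, layer.theta)


def frequency_decompose(
    f: np.ndarray, n_components: int, base_window: int = 11
) -> List[np.ndarray]:
    """Split a (T, D) or (B, T, D) array into frequency components that sum
    exactly to the input.

    Cascade of centered moving averages with halving (odd) windows: component
    0 is the coarsest smooth, each following component is the residual at the
    next finer scale, and the last component is the remaining high-frequency
    residual. The cascade stops early if a window would fall below 3 samples.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    f = np.asarray(f, dtype=np.float64)
    squeeze = f.ndim == 2
    x = Tensor(f[None] if squeeze else f)
    comps = _decompose_tensor(x, n_components, base_window)
    out = [c.data[0] if squeeze else c.data for c in comps]
    return out


def _halving_windows(n_components: int, base_window: int) -> List[int]:
    wins, w = [], base_window | 1  # force odd
    for _ in range(n_components - 1):
        if w < 3:
            break
        wins.append(w)
        w = (w // 2) | 1
    return wins


def _decompose_tensor(x: Tensor, n_components: int, base_window: int) -> List[Tensor]:
    if n_components == 1:
        return [x]
    wins = _halving_windows(n_components, base_window)
    smooths = [moving_average(x, w, axis=1) for w in wins]
    comps: List[Tensor] = []
    prev = None
    for s in smooths:
        comps.append(s if prev is None else s - prev)
        prev = s
    comps.append(x - prev if prev is not None else x)
    return comps


# ---------------------------------------------------------------------------
# trainable regressor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KANConfig:
    n_channels: int = 4
    window_len: int = 30
    embed_dim: int = 16  # D
    kernel_size: int = 5  # M
    n_components: int = 3
    k_schedule: Tuple[int, ...] = (2, 3, 5)  # low -> high frequency
    kan_depth: int = 1  # L: KAN layers per component
    base_window: int = 11
    seed: int = 0

    def __post_init__(self):
        if len(self.k_schedule) != self.n_components:
            raise ValueError("one Chebyshev order per frequency component")
        if any(b > a for a, b in zip(self.k_schedule[1:], self.k_schedule[:-1])):
            raise ValueError("Chebyshev order must be non-decreasing low -> high frequency")


class ChebyshevKANRegressor:
    """Embedding + depthwise conv + multi-order KAN block + linear head."""

    def __init__(self, config: KANConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C, D, M = config.n_channels, config.embed_dim, config.kernel_size
        self.embed_w = Tensor.param(rng.normal(0.0, 1.0 / np.sqrt(C), (C, D)))
        self.embed_b = Tensor.param(np.zeros(D))
        kern = np.zeros((M, D))
        kern[M // 2, :] = 1.0  # start as identity; perturbed to break symmetry
        self.conv_kernels = Tensor.param(kern + rng.normal(0.0, 0.05, (M, D)))
        self.kan_thetas: List[List[Tensor]] = []  # [component][layer] -> (K+1, D, D)
        for K in config.k_schedule:
            scale = np.sqrt(1.0 / (D * (K + 1)))
            self.kan_thetas.append(
                [
                    Tensor.param(rng.normal(0.0, scale, (K + 1, D, D)))
                    for _ in range(config.kan_depth)
                ]
            )
        self.head_w = Tensor.param(rng.normal(0.0, 1.0 / np.sqrt(D), (D, 1)))
        self.head_b = Tensor.param(np.zeros(1))

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> List[Tensor]:
        ps = [self.embed_w, self.embed_b, self.conv_kernels, self.head_w, self.head_b]
        for stack in self.kan_thetas:
            ps.extend(stack)
        return ps

    def parameter_arrays(self) -> dict:
        named = {
            "embed_w": self.embed_w, "embed_b": self.embed_b,
            "conv_kernels": self.conv_kernels,
            "head_w": self.head_w, "head_b": self.head_b,
        }
        for ci, stack in enumerate(self.kan_thetas):
            for li, th in enumerate(stack):
                named[f"theta_c{ci}_l{li}"] = th
        return named

    def forward(self, x: np.ndarray) -> Tensor:
        """(B, T, C) envelope windows -> (B,) force predictions."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        B, T, C = x.shape
        cfg = self.config
        if T != cfg.window_len or C != cfg.n_channels:
            raise ValueError(
                f"expected ({cfg.window_len}, {cfg.n_channels}) windows, got ({T}, {C})"
            )
        h = Tensor(x) @ self.embed_w + self.embed_b  # (B, T, D)
        h = depthwise_conv1d(h, self.conv_kernels)
        comps = _decompose_tensor(h, cfg.n_components, cfg.base_window)
        mixed = None
        for comp, stack in zip(comps, self.kan_thetas):
            z = comp
            for theta in stack:
                z = cheb_layer(z, theta)
            mixed = z if mixed is None else mixed + z
        pooled = mixed.mean(axis=1)  # (B, D)
        out = pooled @ self.head_w + self.head_b  # (B, 1)
        return out.reshape(-1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).data

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Single zip archive: JSON architecture header + flat float64 arrays."""
        header = {
            "model": "chebyshev_kan",
            "config": {
                **{k: getattr(self.config, k) for k in (
                    "n_channels", "window_len", "embed_dim", "kernel_size",
                    "n_components", "kan_depth", "base_window", "seed",
                )},
                "k_schedule": list(self.config.k_schedule),
            },
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("header.json", json.dumps(header, indent=2))
            for name, t in self.parameter_arrays().items():
                buf = io.BytesIO()
                np.save(buf, t.data)
                zf.writestr(f"params/{name}.npy", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ChebyshevKANRegressor":
        with zipfile.ZipFile(path, "r") as zf:
            header = json.loads(zf.read("header.json"))
            cfg = dict(header["config"])
            cfg["k_schedule"] = tuple(cfg["k_schedule"])
            model = cls(KANConfig(**cfg))
            for name, t in model.parameter_arrays().items():
                t.data = np.load(io.BytesIO(zf.read(f"params/{name}.npy")))
        return model
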