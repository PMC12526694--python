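"""Dataset windowing, training loop and evaluation for the force regressors.

Targets are predicted per punch from the pre-contact sEMG envelope window.
Splits are subject-wise (no athlete appears in both partitions), channels are
standardized on training subjects only, and targets are standardized for
optimization but reported back in physical units. Training minimizes
MSE + lambda * sum(w^2) with Adam (alpha = 0.001, lambda = 0.001 by default);
early stopping monitors a held-out validation subset of the training
subjects. Baselines are the two classic recurrent regressors: a single-layer
128-unit tanh RNN and a two-layer 128-unit LSTM, both with dropout 0.2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .autograd import Tensor, slice_last
from .kan import ChebyshevKANRegressor, KANConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "RegressionMetrics",
    "BaselineSpec",
    "WindowSet",
    "make_windows",
    "subject_split",
    "loss",
    "compute_metrics",
    "evaluate",
    "Adam",
    "train",
    "build_baseline",
    "build_model",
    "fit_indicator",
    "RNNRegressor",
    "LSTMRegressor",
]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001  # Adam alpha
    l2_lambda: float = 0.001
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    split: float = 0.8  # subject-wise training fraction
    # Early stopping is opt-in: carving validation subjects out of a 24-athlete
    # training set both discards scarce between-subject information and selects
    # stopping points by the noise of 2-3 subjects; the L2 penalty is the
    # regularizer. Set val_fraction > 0 to enable patience-based stopping.
    val_fraction: float = 0.0
    patience: int = 20

    def __post_init__(self):
        if self.learning_rate <= 0 or self.l2_lambda < 0:
            raise ValueError("need alpha > 0 and lambda >= 0")
        if not 0 < self.split < 1:
            raise ValueError("split must be in (0, 1)")


@dataclass(frozen=True)
class RegressionMetrics:
    rmse: float
    mae: float
    r2: float


@dataclass(frozen=True)
class BaselineSpec:
    kind: str  # "rnn" | "lstm"
    hidden_units: int = 128
    dropout: float = 0.2

    @property
    def layers(self) -> int:
        return 1 if self.kind == "rnn" else 2

    def __post_init__(self):
        if self.kind not in ("rnn", "lstm"):
            raise ValueError("kind must be 'rnn' or 'lstm'")


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Paired (envelope window, indicator value) examples for one condition."""

    X: np.ndarray  # (N, T, C)
    y: np.ndarray  # (N,)
    subjects: np.ndarray  # (N,) subject ids
    indicator: str
    condition: str
    n_dropped: int = 0


def make_windows(
    envelopes: Dict[tuple, np.ndarray],
    kinetics,  # tidy DataFrame: subject_id, condition, punch_index, indicators
    indicator: str,
    condition: str,
    downsample: int = 10,
) -> WindowSet:
    """One example per valid punch of ``condition``.

    ``envelopes`` maps (subject_id, condition, punch_index) to a (T, C)
    envelope array. Punches whose indicator is undefined (e.g. t500N below a
    400 N peak) are dropped with a logged count. The envelope is decimated by
    ``downsample`` (the 50 ms moving average leaves no content near the
    decimated Nyquist).
    """
    sel = kinetics[kinetics.condition == condition]
    X, y, subs, dropped = [], [], [], 0
    for r in sel.itertuples():
        val = getattr(r, indicator)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            dropped += 1
            continue
        env = envelopes[(r.subject_id, r.condition, r.punch_index)]
        X.append(env[::downsample])
        y.append(val)
        subs.append(r.subject_id)
    if dropped:
        logger.info("dropped %d punches with undefined %s", dropped, indicator)
    if not X:
        raise ValueError(f"no valid punches for {indicator} under {condition}")
    return WindowSet(
        X=np.asarray(X, dtype=np.float64),
        y=np.asarray(y, dtype=np.float64),
        subjects=np.asarray(subs),
        indicator=indicator,
        condition=condition,
        n_dropped=dropped,
    )


def subject_split(subjects: np.ndarray, train_frac: float, seed: int):
    """Subject-wise partition; returns (train_mask, test_mask)."""
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    n_train = int(round(train_frac * len(uniq)))
    n_train = min(max(n_train, 1), len(uniq) - 1)
    train_subjects = set(perm[:n_train])
    train_mask = np.array([s in train_subjects for s in subjects])
    return train_mask, ~train_mask


@dataclass
class Standardizer:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, axis) -> "Standardizer":
        mean = X.mean(axis=axis, keepdims=True)
        std = X.std(axis=axis, keepdims=True)
        std = np.where(std < 1e-12, 1.0, std)
        return cls(mean, std)

    def transform(self, X):
        return (X - self.mean) / self.std

    def inverse(self, Xs):
        return Xs * self.std + self.mean


# ---------------------------------------------------------------------------
# loss & metrics
# ---------------------------------------------------------------------------

def loss(pred, target, params: Sequence = (), l2_lambda: float = 0.0) -> float:
    """MSE + lambda * sum of squared parameters (plain-number version)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target must have equal length")
    mse = float(np.mean((pred - target) ** 2))
    reg = sum(float(np.sum(np.square(getattr(w, "data", w)))) for w in params)
    return mse + l2_lambda * reg


def compute_metrics(y, y_pred) -> RegressionMetrics:
    """RMSE, MAE and R^2 = 1 - SS_res/SS_tot."""
    y = np.asarray(y, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("target variance is zero; R^2 undefined")
    err = y_pred - y
    return RegressionMetrics(
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        r2=1.0 - float(np.sum(err**2)) / ss_tot,
    )


def evaluate(model, X, y, x_scaler=None, y_scaler=None) -> RegressionMetrics:
    """Metrics in physical target units (predictions un-standardized)."""
    Xs = x_scaler.transform(X) if x_scaler is not None else X
    pred = model.predict(Xs)
    if y_scaler is not None:
        pred = y_scaler.inverse(pred)
    return compute_metrics(y, pred)


# ---------------------------------------------------------------------------
# optimizer & loop
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: List[Tensor], lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _regularized_loss(model, X, y, lam, train_mode, rng) -> Tensor:
    pred = (
        model.forward(X, train=train_mode, rng=rng)
        if isinstance(model, (RNNRegressor, LSTMRegressor))
        else model.forward(X)
    )
    diff = pred - y
    total = (diff * diff).mean()
    if lam > 0:
        for p in model.parameters():
            total = total + lam * (p * p).sum()
    return total


def train(model, X, y, config: TrainingConfig, X_val=None, y_val=None):
    """Adam on MSE + L2; returns (model, history dict).

    Deterministic given ``config.seed``. Early stopping (restore-best) when a
    validation set is provided; aborts with diagnostics on divergence.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = len(y)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        lam = config.l2_lambda
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            mse = _regularized_loss(model, X[idx], y[idx], 0.0, True, rng)
            if not np.isfinite(mse.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={mse.data!r})"
                )
            mse.backward()
            # L2 term folded in analytically: d(lam*sum w^2)/dw = 2*lam*w
            reg = 0.0
            if lam > 0:
                for p in model.parameters():
                    p.grad = (p.grad if p.grad is not None else 0.0) + 2.0 * lam * p.data
                    reg += float(np.sum(p.data**2))
            opt.step()
            ep_loss += (float(mse.data) + lam * reg) * len(idx)
        history["train_loss"].append(ep_loss / n)
        if X_val is not None and len(y_val):
            pred = model.predict(X_val)
            val = float(np.mean((pred - y_val) ** 2))
            history["val_loss"].append(val)
            if val < best_val - 1e-9:
                best_val, since_best = val, 0
                best_state = [p.data.copy() for p in model.parameters()]
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best_state is not None:
        for p, d in zip(model.parameters(), best_state):
            p.data = d
    return model, history


# ---------------------------------------------------------------------------
# recurrent baselines
# ---------------------------------------------------------------------------

class _Recurrent:
    """Shared machinery: last-hidden-state -> dropout -> linear head."""

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False).data

    def _dropout(self, h: Tensor, train: bool, rng) -> Tensor:
        if not train or self.dropout <= 0:
            return h
        keep = 1.0 - self.dropout
        mask = (rng.random(h.data.shape) < keep) / keep
        return h * Tensor(mask)


class RNNRegressor(_Recurrent):
    """Single recurrent layer, 128 tanh units, dropout 0.2 before the head."""

    def __init__(self, n_channels: int, window_len: int, hidden: int = 128,
                 dropout: float = 0.2, seed: int = 0):
        rng = np.random.default_rng(seed)
        H = hidden
        self.hidden, self.dropout = H, dropout
        self.w_ih = Tensor.param(rng.normal(0, 1 / np.sqrt(n_channels), (n_channels, H)))
        self.w_hh = Tensor.param(rng.normal(0, 1 / np.sqrt(H), (H, H)))
        self.b = Tensor.param(np.zeros(H))
        self.head_w = Tensor.param(rng.normal(0, 1 / np.sqrt(H), (H, 1)))
        self.head_b = Tensor.param(np.zeros(1))

    def parameters(self):
        return [self.w_ih, self.w_hh, self.b, self.head_w, self.head_b]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> Tensor:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        B, T, C = x.shape
        h = Tensor(np.zeros((B, self.hidden)))
        for t in range(T):
            h = (Tensor(x[:, t, :]) @ self.w_ih + h @ self.w_hh + self.b).tanh()
        h = self._dropout(h, train, rng or np.random.default_rng(0))
        return (h @ self.head_w + self.head_b).reshape(-1)


class LSTMRegressor(_Recurrent):
    """Two stacked LSTM layers (128 units each), dropout 0.2 between layers
    and before the head; forget/input/output gates in the standard form."""

    def __init__(self, n_channels: int, window_len: int, hidden: int = 128,
                 dropout: float = 0.2, seed: int = 0):
        rng = np.random.default_rng(seed)
        H = hidden
        self.hidden, self.dropout = H, dropout
        self.layers = []
        for layer, c_in in enumerate((n_channels, H)):
            w_ih = Tensor.param(rng.normal(0, 1 / np.sqrt(c_in), (c_in, 4 * H)))
            w_hh = Tensor.param(rng.normal(0, 1 / np.sqrt(H), (H, 4 * H)))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.layers.append((w_ih, w_hh, Tensor.param(b)))
        self.head_w = Tensor.param(rng.normal(0, 1 / np.sqrt(H), (H, 1)))
        self.head_b = Tensor.param(np.zeros(1))

    def parameters(self):
        ps = []
        for w_ih, w_hh, b in self.layers:
            ps.extend([w_ih, w_hh, b])
        ps.extend([self.head_w, self.head_b])
        return ps

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> Tensor:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        B, T, C = x.shape
        rng = rng or np.random.default_rng(0)
        H = self.hidden
        inputs = [Tensor(x[:, t, :]) for t in range(T)]
        for li, (w_ih, w_hh, b) in enumerate(self.layers):
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
            outs = []
            for xt in inputs:
                a = xt @ w_ih + h @ w_hh + b
                i = slice_last(a, 0, H).sigmoid()
                f = slice_last(a, H, 2 * H).sigmoid()
                g = slice_last(a, 2 * H, 3 * H).tanh()
                o = slice_last(a, 3 * H, 4 * H).sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outs.append(h)
            if li + 1 < len(self.layers):
                inputs = [self._dropout(h_t, train, rng) for h_t in outs]
            else:
                h_last = outs[-1]
        h_last = self._dropout(h_last, train, rng)
        return (h_last @ self.head_w + self.head_b).reshape(-1)


def build_baseline(spec: BaselineSpec, n_channels: int, window_len: int, seed: int = 0):
    cls = RNNRegressor if spec.kind == "rnn" else LSTMRegressor
    return cls(n_channels, window_len, hidden=spec.hidden_units,
               dropout=spec.dropout, seed=seed)


def build_model(kind: str, n_channels: int, window_len: int, seed: int = 0,
                kan_config: Optional[KANConfig] = None):
    if kind == "kan":
        cfg = kan_config or KANConfig(n_channels=n_channels, window_len=window_len, seed=seed)
        cfg = replace(cfg, n_channels=n_channels, window_len=window_len, seed=seed)
        return ChebyshevKANRegressor(cfg)
    return build_baseline(BaselineSpec(kind=kind), n_channels, window_len, seed)


# ---------------------------------------------------------------------------
# end-to-end fit for one (indicator, condition)
# ---------------------------------------------------------------------------

def fit_indicator(windows: WindowSet, model_kind: str, config: TrainingConfig,
                  kan_config: Optional[KANConfig] = None) -> dict:
    """Subject-wise split, standardization, training, train/test metrics."""
    train_mask, test_mask = subject_split(windows.subjects, config.split, config.seed)
    X_tr, y_tr = windows.X[train_mask], windows.y[train_mask]
    X_te, y_te = windows.X[test_mask], windows.y[test_mask]

    x_scaler = Standardizer.fit(X_tr, axis=(0, 1))  # per channel
    y_scaler = Standardizer.fit(y_tr, axis=0)
    Xs, ys = x_scaler.transform(X_tr), y_scaler.transform(y_tr)

    # validation subjects carved out of the training subjects
    tr_subj = windows.subjects[train_mask]
    val_frac = config.val_fraction
    if val_frac > 0 and len(np.unique(tr_subj)) >= 3:
        core_mask, val_mask = subject_split(tr_subj, 1.0 - val_frac, config.seed + 1)
    else:
        core_mask = np.ones(len(ys), dtype=bool)
        val_mask = ~core_mask
    model = build_model(model_kind, windows.X.shape[2], windows.X.shape[1],
                        seed=config.seed, kan_config=kan_config)
    model, history = train(
        model, Xs[core_mask], ys[core_mask], config,
        X_val=Xs[val_mask] if val_mask.any() else None,
        y_val=ys[val_mask] if val_mask.any() else None,
    )
    return {
        "model": model,
        "history": history,
        "train_metrics": evaluate(model, X_tr, y_tr, x_scaler, y_scaler),
        "test_metrics": evaluate(model, X_te, y_te, x_scaler, y_scaler),
        "n_train": int(train_mask.sum()),
        "n_test": int(test_mask.sum()),
    }
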