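"""Surface-EMG envelope extraction.

The chain is the standard sEMG amplitude pipeline: band-pass filter
(5-500 Hz, 4th-order Butterworth), full-wave rectification, and a 50 ms
centered moving-average smoother. Filtering is zero-phase by default so the
envelope stays time-aligned with force events; a causal mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

__all__ = ["EMGTrace", "FilterSpec", "bandpass", "rectify", "smooth", "preprocess"]

STAGES = ("raw", "filtered", "rectified", "envelope")


@dataclass
class EMGTrace:
    """One channel-set of sEMG samples.

    samples: (T, C) array, mV (arbitrary calibration); fs in Hz.
    ``stage`` tracks the position in the processing chain.
    """

    samples: np.ndarray
    fs: float = 1000.0
    channel_labels: tuple = ()
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (T, C) array")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i + 1}" for i in range(self.samples.shape[1]))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class FilterSpec:
    low_cut: float = 5.0
    high_cut: float = 500.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order sections for the band-pass design.

    A high cut at or above Nyquist (the nominal 500 Hz band at fs=1000)
    is clamped just below Nyquist, with a warning.
    """
    nyq = fs / 2.0
    high = spec.high_cut
    if high >= nyq:
        high = 0.99995 * nyq
        warnings.warn(
            f"high_cut {spec.high_cut} Hz >= Nyquist ({nyq} Hz); clamped to {high:.3f} Hz",
            stacklevel=2,
        )
    return signal.butter(spec.order, [spec.low_cut, high], btype="bandpass", fs=fs, output="sos")


def bandpass(trace: EMGTrace, spec: Optional[FilterSpec] = None) -> EMGTrace:
    """Band-pass filter each channel; length-preserving."""
    spec = spec or FilterSpec()
    if trace.stage != "raw":
        raise ValueError(f"bandpass expects a raw trace, got stage={trace.stage!r}")
    if not np.all(np.isfinite(trace.samples)):
        raise ValueError("non-finite samples")
    sos = design_sos(spec, trace.fs)
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, trace.samples, axis=0)
    else:
        out = signal.sosfilt(sos, trace.samples, axis=0)
    meta = dict(trace.meta, filter_spec=spec)
    return EMGTrace(out, trace.fs, trace.channel_labels, "filtered", meta)


def rectify(trace: EMGTrace) -> EMGTrace:
    if trace.stage != "filtered":
        raise ValueError(f"rectify expects a filtered trace, got stage={trace.stage!r}")
    return EMGTrace(
        np.abs(trace.samples), trace.fs, trace.channel_labels, "rectified", dict(trace.meta)
    )


def moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar mean along axis 0 with shrinking windows at the edges.

    For even windows the extra sample sits on the trailing side
    (window covers ``[i - w//2, i + w - 1 - w//2]``).
    """
    T = x.shape[0]
    if window < 1:
        raise ValueError("window must cover at least one sample")
    if window > T:
        raise ValueError(f"window ({window}) longer than trace ({T})")
    left = window // 2
    right = window - 1 - left
    idx = np.arange(T)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, T - 1)
    csum = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)], axis=0)
    counts = (hi - lo + 1).astype(np.float64).reshape((T,) + (1,) * (x.ndim - 1))
    return (csum[hi + 1] - csum[lo]) / counts


def smooth(trace: EMGTrace, window_ms: float = 50.0) -> EMGTrace:
    """Moving-average smoothing; window rounded to samples (50 at 1 kHz)."""
    if trace.stage != "rectified":
        raise ValueError(f"smooth expects a rectified trace, got stage={trace.stage!r}")
    window = int(round(window_ms * trace.fs / 1000.0))
    if window < 1:
        raise ValueError("window_ms shorter than one sample period")
    out = moving_mean(trace.samples, window)
    meta = dict(trace.meta, smooth_window_ms=window_ms, smooth_window_samples=window)
    return EMGTrace(out, trace.fs, trace.channel_labels, "envelope", meta)


def preprocess(
    trace: EMGTrace, spec: Optional[FilterSpec] = None, window_ms: float = 50.0
) -> EMGTrace:
    """Full chain: band-pass -> full-wave rectification -> moving average."""
    return smooth(rectify(bandpass(trace, spec)), window_ms)
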