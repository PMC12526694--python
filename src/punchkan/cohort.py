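"""Seeded synthetic repeated-measures punch cohort.

Emulates a 30-athlete crossover study with three NMES conditions (Sham,
upper-limb, lower-limb stimulation): each subject throws 126 maximal punches
per condition against a 0-2000 N transducer sampled at 1 kHz while 4-channel
sEMG is recorded at 1 kHz.

Per-punch kinetics are drawn from per-condition calibration cells
(relative peak force, impulse, F5ms, tF50%, tF90% means/SDs of the original
study) with a latent per-subject "athlete quality" intercept shared across
conditions and indicators — this is what gives the repeated-measures
structure its within-subject correlation. Each draw is realized as a force
waveform: a monotone piecewise-linear rise through the anchors
(0,0) -> (5 ms, F5ms) -> (tF50, 0.5*Fpeak) -> (tF90, 0.9*Fpeak) -> (t_peak, Fpeak)
followed by an exponential decay; t_peak is solved in closed form so the
rise integrates exactly to the drawn impulse.

The paired sEMG window is band-limited Gaussian carrier noise amplitude-
modulated by a smooth pre-contact burst whose amplitude encodes the punch's
peak force through a saturating activation map, corrupted so that a stated
``noise_share`` of peak-force variance is unexplainable from the envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .kinetics import ForceTrace, SENSOR_RANGE_N
from .preprocessing import EMGTrace, FilterSpec, design_sos

__all__ = [
    "CONDITIONS",
    "SubjectProfile",
    "ConditionSpec",
    "PunchPulseParams",
    "CouplingSpec",
    "CohortConfig",
    "CohortDataset",
    "default_condition_specs",
    "solve_t_peak",
    "sample_punch_params",
    "synthesize_force_pulse",
    "synthesize_emg",
    "calibrate_coupling",
    "sample_cohort_params",
    "generate_cohort",
]

CONDITIONS = ("Sham", "U-NMES", "L-NMES")

# Published condition cells of the original study (per-condition mean +- SD
# of per-subject means): relative peak force (N/kg), impulse (N*s),
# tF50% (ms), tF90% (ms), F5ms (N).
_CONDITION_CELLS = {
    "Sham": dict(rel=(22.7, 5.5), imp=(11.3, 1.2), t50=(6.9, 1.5), t90=(12.4, 1.9), f5=(511.0, 77.0)),
    "U-NMES": dict(rel=(24.5, 4.7), imp=(13.2, 0.9), t50=(6.5, 1.3), t90=(12.3, 1.7), f5=(631.0, 89.0)),
    "L-NMES": dict(rel=(28.2, 3.2), imp=(16.6, 2.3), t50=(6.2, 1.6), t90=(11.8, 2.1), f5=(754.0, 94.0)),
}
BODY_MASS_KG = (68.2, 8.3)  # cohort demographics
T5 = 0.005  # F5ms anchor time (s)


@dataclass(frozen=True)
class SubjectProfile:
    """One athlete.

    ``subject_effect`` is the standardized latent intercept (z-score scale,
    neutral 0) shared across conditions; ``emg_gain`` is the per-subject
    sEMG amplitude factor (electrode placement/impedance variation).
    """

    subject_id: str
    body_mass: float
    subject_effect: float = 0.0
    emg_gain: float = 1.0

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")


@dataclass(frozen=True)
class ConditionSpec:
    condition: str
    mean_rel_peak_force: float
    sd_rel_peak_force: float
    mean_impulse: float
    sd_impulse: float
    mean_t50: float  # ms
    sd_t50: float
    mean_t90: float  # ms
    sd_t90: float
    mean_f5ms: float
    sd_f5ms: float

    def __post_init__(self):
        if not 0 < self.mean_t50 < self.mean_t90:
            raise ValueError("need 0 < t50 < t90")


def default_condition_specs() -> Dict[str, ConditionSpec]:
    out = {}
    for name, c in _CONDITION_CELLS.items():
        out[name] = ConditionSpec(
            condition=name,
            mean_rel_peak_force=c["rel"][0],
            sd_rel_peak_force=c["rel"][1],
            mean_impulse=c["imp"][0],
            sd_impulse=c["imp"][1],
            mean_t50=c["t50"][0],
            sd_t50=c["t50"][1],
            mean_t90=c["t90"][0],
            sd_t90=c["t90"][1],
            mean_f5ms=c["f5"][0],
            sd_f5ms=c["f5"][1],
        )
    return out


@dataclass(frozen=True)
class PunchPulseParams:
    """Waveform anchors of one punch (times in seconds, forces in N)."""

    f_peak: float
    f5ms: float
    t50: float
    t90: float
    t_peak: float
    decay_tau: float = 0.02
    contact_time: float = 0.1
    punch_type: str = "straight"

    def __post_init__(self):
        if self.f_peak < 0:
            raise ValueError("f_peak must be nonnegative")
        if self.f_peak > SENSOR_RANGE_N:
            raise ValueError(f"f_peak {self.f_peak:.1f} N exceeds sensor range ({SENSOR_RANGE_N} N)")
        if self.f_peak > 0:
            if not (T5 < self.t50 < self.t90 < self.t_peak):
                raise ValueError("need 5 ms < t50 < t90 < t_peak")
            if not (0 <= self.f5ms < 0.5 * self.f_peak):
                raise ValueError("F5ms anchor must lie below half of peak force")


@dataclass(frozen=True)
class CouplingSpec:
    """sEMG-envelope -> punch-kinetics coupling.

    Each muscle channel's burst amplitude encodes one kinetic quantity on a
    force-like scale through the saturating activation map
    f = f_max * a / (a + a_half) (strictly increasing): the mass-normalized
    peak force (relative peak force x reference mass — neural activation
    tracks strength, not body size), the absolute peak force, F5ms, and the
    impulse (x ``impulse_scale`` to bring N*s onto the force scale). This is
    the intermuscular-coordination surrogate that lets a multichannel model
    recover every reported indicator. ``noise_share`` is the fraction of each
    encoded quantity's variance the envelope cannot explain; the per-channel
    multiplicative noise SDs (``noise_sigma``) are derived from the realized
    cohort by :func:`calibrate_coupling`.
    """

    f_max: float = 2500.0
    a_half: float = 0.15  # mV
    noise_share: float = 0.25
    channels: int = 4
    channel_targets: Tuple[str, ...] = ("relative", "absolute", "f5ms", "impulse")
    channel_weights: Tuple[float, ...] = (1.0, 0.85, 0.7, 0.55)
    reference_mass: float = BODY_MASS_KG[0]  # kg
    impulse_scale: float = 100.0  # N*s -> force-like scale for the map
    noise_sigma: Optional[Tuple[float, ...]] = None  # per channel

    def __post_init__(self):
        if not 0 <= self.noise_share < 1:
            raise ValueError("noise_share must be in [0, 1)")
        if self.f_max <= SENSOR_RANGE_N or self.a_half <= 0:
            raise ValueError("invalid activation map")
        if len(self.channel_weights) != self.channels:
            raise ValueError("one weight per channel")
        if len(self.channel_targets) != self.channels:
            raise ValueError("one encoded quantity per channel")
        bad = set(self.channel_targets) - {"relative", "absolute", "f5ms", "impulse"}
        if bad:
            raise ValueError(f"unknown channel targets {bad}")

    def activation(self, a):
        a = np.asarray(a, dtype=np.float64)
        return self.f_max * a / (a + self.a_half)

    def inverse(self, f):
        f = np.asarray(f, dtype=np.float64)
        if np.any(f >= self.f_max):
            raise ValueError("force at or above activation-map asymptote")
        return self.a_half * f / (self.f_max - f)

    def channel_values(self, p: "PunchPulseParams", body_mass: float) -> np.ndarray:
        """Force-scale quantity encoded by each channel for one punch."""
        impulse = rise_area_to_t90(p.f_peak, p.f5ms, p.t50, p.t90) + 0.95 * p.f_peak * (
            p.t_peak - p.t90
        )
        lookup = {
            "relative": p.f_peak / body_mass * self.reference_mass,
            "absolute": p.f_peak,
            "f5ms": p.f5ms,
            "impulse": impulse * self.impulse_scale,
        }
        return np.array([lookup[t] for t in self.channel_targets])


def calibrate_coupling(coupling: CouplingSpec, channel_values: np.ndarray) -> CouplingSpec:
    """Fix per-channel ``noise_sigma`` so corr^2(envelope-implied quantity,
    true quantity) equals 1 - noise_share over the cohort.

    ``channel_values``: (n_punches, channels) array of encoded quantities.
    """
    v = np.atleast_2d(np.asarray(channel_values, dtype=np.float64))
    if coupling.noise_share == 0 or v.shape[0] < 2:
        return replace(coupling, noise_sigma=tuple(0.0 for _ in range(coupling.channels)))
    ratio = coupling.noise_share / (1.0 - coupling.noise_share)
    sigma = tuple(
        math.sqrt(ratio * v[:, c].var() / np.mean(v[:, c] ** 2))
        for c in range(coupling.channels)
    )
    return replace(coupling, noise_sigma=sigma)


@dataclass
class CohortConfig:
    conditions: Dict[str, ConditionSpec] = field(default_factory=default_condition_specs)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    n_subjects: int = 30
    punch_count_per_session: int = 126
    subject_rho: float = 0.7  # loading of the shared athlete intercept
    force_factor: float = 0.7  # coupling of force indicators within (subject, condition)
    punch_cv: float = 0.03  # shared punch-intensity CV
    punch_cv_idio: float = 0.015  # indicator-specific punch CV
    temporal_effect: str = "null"  # "null": condition-pooled tF50/tF90 means
    mass_mean: float = BODY_MASS_KG[0]
    mass_sd: float = BODY_MASS_KG[1]
    mass_bounds: Tuple[float, float] = (45.0, 90.0)
    emg_gain_cv: float = 0.10
    fs: float = 1000.0
    emg_window_ms: float = 300.0
    decay_tau: float = 0.02
    contact_time: float = 0.1
    subject_peak_cap: float = 1950.0  # N, keeps punches inside the sensor range
    punch_peak_cap: float = 1995.0  # N
    punch_type_mix: Tuple[Tuple[str, float], ...] = (
        ("straight", 0.6),
        ("hook", 0.3),
        ("swing", 0.1),
    )
    punch_type_scale: Tuple[Tuple[str, float], ...] = (
        ("straight", 1.0),
        ("hook", 1.03),
        ("swing", 0.97),
    )

    def __post_init__(self):
        if not 0 <= self.subject_rho < 1:
            raise ValueError("subject_rho in [0, 1)")
        if self.temporal_effect not in ("null", "table"):
            raise ValueError("temporal_effect must be 'null' or 'table'")


# ---------------------------------------------------------------------------
# closed-form pulse geometry
# ---------------------------------------------------------------------------

def rise_area_to_t90(f_peak: float, f5: float, t50: float, t90: float) -> float:
    """Integral of the piecewise-linear rise from contact to t90 (N*s)."""
    return (
        0.5 * f5 * T5
        + 0.5 * (f5 + 0.5 * f_peak) * (t50 - T5)
        + 0.7 * f_peak * (t90 - t50)
    )


def solve_t_peak(f_peak, f5, t50, t90, impulse):
    """Solve t_peak so the piecewise-linear rise integrates to ``impulse``.

    impulse = A(t90) + 0.95 * f_peak * (t_peak - t90) with A the rise area up
    to t90.  Raises (scalar input) when the drawn impulse is too small to
    place t_peak after t90.
    """
    area = rise_area_to_t90(np.asarray(f_peak, float), np.asarray(f5, float),
                            np.asarray(t50, float), np.asarray(t90, float))
    t_peak = np.asarray(t90, float) + (np.asarray(impulse, float) - area) / (
        0.95 * np.asarray(f_peak, float)
    )
    if np.ndim(t_peak) == 0:
        if t_peak <= t90 + 1e-12:
            raise ValueError("impulse draw incompatible with timing draws (t_peak <= t90)")
        return float(t_peak)
    return t_peak


def sample_punch_params(
    cond: ConditionSpec,
    subj: SubjectProfile,
    rng: np.random.Generator,
    *,
    subject_rho: float = 0.7,
    jitter: bool = True,
    decay_tau: float = 0.02,
    contact_time: float = 0.1,
    max_attempts: int = 100,
) -> PunchPulseParams:
    """Draw one punch for one subject under one condition.

    With ``jitter=False`` and a neutral subject (effect 0, mass at the
    condition-independent default) the draw sits exactly at the condition
    means. Incompatible draws (t_peak <= t90, anchor ordering, sensor range)
    are redrawn up to ``max_attempts`` times.
    """
    s = math.sqrt(1.0 - subject_rho**2)
    for _ in range(max_attempts):
        z = rng.standard_normal(5) if jitter else np.zeros(5)
        rel = cond.mean_rel_peak_force + cond.sd_rel_peak_force * (
            subject_rho * subj.subject_effect + s * z[0]
        )
        impulse = cond.mean_impulse + cond.sd_impulse * (
            subject_rho * subj.subject_effect + s * z[1]
        )
        f5 = cond.mean_f5ms + cond.sd_f5ms * (subject_rho * subj.subject_effect + s * z[2])
        t50 = (cond.mean_t50 + cond.sd_t50 * s * z[3]) / 1000.0
        t90 = (cond.mean_t90 + cond.sd_t90 * s * z[4]) / 1000.0
        f_peak = rel * subj.body_mass
        if not (0 < f_peak <= SENSOR_RANGE_N and impulse > 0):
            continue
        if not (T5 * 1.02 < t50 < t90 and 0 < f5 < 0.5 * f_peak):
            continue
        try:
            t_peak = solve_t_peak(f_peak, f5, t50, t90, impulse)
        except ValueError:
            continue
        return PunchPulseParams(
            f_peak=f_peak, f5ms=f5, t50=t50, t90=t90, t_peak=t_peak,
            decay_tau=decay_tau, contact_time=contact_time,
        )
    raise ValueError(f"no admissible punch parameters after {max_attempts} attempts")


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def synthesize_force_pulse(
    p: PunchPulseParams, fs: float = 1000.0, duration: Optional[float] = None
) -> ForceTrace:
    """Realize the anchor geometry as a sampled force trace.

    Zero before contact; piecewise-linear monotone rise through the anchors;
    exponential decay with time constant ``decay_tau`` after the peak. The
    contact instant is snapped to the sample grid so the trace starts its
    rise exactly at a sample.
    """
    if p.f_peak > SENSOR_RANGE_N:
        raise ValueError("f_peak exceeds sensor range")
    if duration is None:
        duration = p.contact_time + (p.t_peak if p.f_peak > 0 else 0.0) + 6.0 * p.decay_tau
    n = int(round(duration * fs))
    if p.f_peak == 0:
        return ForceTrace(np.zeros(n), fs)
    c0 = int(round(p.contact_time * fs))
    t = np.arange(n) / fs - c0 / fs  # time relative to contact
    anchors_t = np.array([0.0, T5, p.t50, p.t90, p.t_peak])
    anchors_f = np.array([0.0, p.f5ms, 0.5 * p.f_peak, 0.9 * p.f_peak, p.f_peak])
    if np.any(np.diff(anchors_t) <= 0) or np.any(np.diff(anchors_f) < 0):
        raise ValueError("rise anchors must be strictly ordered and monotone")
    x = np.interp(t, anchors_t, anchors_f, left=0.0)
    decay = t > p.t_peak
    x[decay] = p.f_peak * np.exp(-(t[decay] - p.t_peak) / p.decay_tau)
    x[t < 0] = 0.0
    return ForceTrace(x, fs)


_carrier_sos_cache: dict = {}


def _carrier_sos(fs: float) -> np.ndarray:
    key = float(fs)
    if key not in _carrier_sos_cache:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _carrier_sos_cache[key] = design_sos(FilterSpec(5.0, 500.0, 4), fs)
    return _carrier_sos_cache[key]


def synthesize_emg(
    p: PunchPulseParams,
    coupling: CouplingSpec,
    subj: SubjectProfile,
    rng: np.random.Generator,
    fs: float = 1000.0,
    window_ms: float = 300.0,
) -> EMGTrace:
    """Pre-contact sEMG window whose burst amplitude encodes peak force.

    Each channel is unit-RMS band-limited (5-500 Hz) Gaussian carrier noise
    amplitude-modulated by a raised-cosine burst. Channel c's burst amplitude
    is activation_map^-1(v_c * (1 + eta_c)), eta_c ~ N(0, noise_sigma_c),
    where v_c is the kinetic quantity that channel encodes (see
    ``CouplingSpec.channel_targets``). All channels share the subject's
    ``emg_gain`` (electrode placement factor) and fixed per-muscle weights.
    """
    n = int(round(window_ms * fs / 1000.0))
    c = coupling.channels
    if p.f_peak == 0:
        return EMGTrace(np.zeros((n, c)), fs, stage="raw")
    if coupling.noise_sigma is None:
        if coupling.noise_share > 0:
            raise ValueError(
                "coupling with noise_share > 0 must be calibrated first "
                "(see calibrate_coupling)"
            )
        sigma = np.zeros(c)
    else:
        sigma = np.asarray(coupling.noise_sigma)
    values = coupling.channel_values(p, subj.body_mass)
    eta = sigma * rng.standard_normal(c)
    v_emg = np.clip(values * (1.0 + eta), 1.0, 0.98 * coupling.f_max)
    amps = coupling.inverse(v_emg)

    # raised-cosine burst peaking ~130 ms before contact
    t = np.arange(n)
    start, width = int(0.2 * n), int(0.733 * n)
    env = np.zeros(n)
    inside = (t >= start) & (t < start + width)
    env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[inside] - start) / width))

    white = rng.standard_normal((n, c))
    carrier = _signal.sosfiltfilt(_carrier_sos(fs), white, axis=0)
    carrier /= np.sqrt(np.mean(carrier**2, axis=0, keepdims=True))
    weights = np.asarray(coupling.channel_weights)
    samples = subj.emg_gain * env[:, None] * carrier * (amps * weights)[None, :]
    return EMGTrace(
        samples, fs, stage="raw",
        meta={"burst_amplitudes": amps, "encoded_values": v_emg, "true_values": values},
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _pooled(cells, key):
    means = [getattr(c, f"mean_{key}") for c in cells]
    sds = [getattr(c, f"sd_{key}") for c in cells]
    return float(np.mean(means)), float(np.sqrt(np.mean(np.square(sds))))


def _redraw(draw, valid, max_attempts=100, what="draw"):
    """Vectorized rejection sampling: replace invalid entries with fresh draws.

    ``draw()`` returns a full-size sample each call; only entries failing
    ``valid`` are replaced, so accepted entries keep their first value.
    """
    x = draw()
    for _ in range(max_attempts):
        bad = ~valid(x)
        if not bad.any():
            return x
        fresh = draw()
        mask = bad if x.ndim == 1 else bad[:, None]
        x = np.where(mask, fresh, x)
    if (~valid(x)).any():
        raise ValueError(f"could not find admissible {what} after {max_attempts} attempts")
    return x


def sample_cohort_params(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw the full per-punch kinetic-parameter table (no waveforms).

    Deterministic given the seed. One row per (subject, condition, punch)
    with the waveform anchors and the implied ground-truth indicators.
    """
    rng = np.random.default_rng(seed)
    n, conds = config.n_subjects, list(config.conditions)
    k = len(conds)
    m = config.punch_count_per_session
    rho, s = config.subject_rho, math.sqrt(1.0 - config.subject_rho**2)
    omega, somega = config.force_factor, math.sqrt(1.0 - config.force_factor**2)

    z_subj = rng.standard_normal(n)
    z_subj_t = rng.standard_normal(n)  # separate intercept for temporal indicators
    rho_t = 0.5
    s_t = math.sqrt(1.0 - rho_t**2)
    emg_gain = np.exp(rng.normal(-0.5 * config.emg_gain_cv**2, config.emg_gain_cv, n))

    # subject x condition indicator levels
    rel = np.empty((n, k))
    imp = np.empty((n, k))
    f5 = np.empty((n, k))
    t50 = np.empty((n, k))
    t90 = np.empty((n, k))
    pooled_t50 = _pooled(config.conditions.values(), "t50")
    pooled_t90 = _pooled(config.conditions.values(), "t90")
    z_force = rng.standard_normal((n, k))
    for j, name in enumerate(conds):
        c = config.conditions[name]

        def level(mu, sd, coupled=True, j=j):
            idio = rng.standard_normal(n)
            if coupled:
                mix = omega * z_force[:, j] + somega * idio
                return mu + sd * (rho * z_subj + s * mix)
            return mu + sd * (rho_t * z_subj_t + s_t * idio)

        rel[:, j] = _redraw(
            lambda c=c: level(c.mean_rel_peak_force, c.sd_rel_peak_force),
            lambda x: x > 8.0,
            what="relative peak force",
        )
        imp[:, j] = _redraw(
            lambda c=c: level(c.mean_impulse, c.sd_impulse),
            lambda x: x > 2.0,
            what="impulse",
        )
        f5[:, j] = _redraw(
            lambda c=c: level(c.mean_f5ms, c.sd_f5ms),
            lambda x: x > 100.0,
            what="F5ms",
        )
        mu_t50, sd_t50 = (
            (c.mean_t50, c.sd_t50) if config.temporal_effect == "table" else pooled_t50
        )
        mu_t90, sd_t90 = (
            (c.mean_t90, c.sd_t90) if config.temporal_effect == "table" else pooled_t90
        )
        t50[:, j] = _redraw(
            lambda mu=mu_t50, sd=sd_t50: level(mu, sd, coupled=False),
            lambda x: x > 5.3,
            what="tF50",
        )
        t90[:, j] = np.maximum(
            _redraw(
                lambda mu=mu_t90, sd=sd_t90: level(mu, sd, coupled=False),
                lambda x: x > 7.0,
                what="tF90",
            ),
            t50[:, j] + 1.2,
        )

    # body mass: truncated so subject-level peak force respects the sensor cap;
    # heavier athletes carry lower relative force, never the other way around
    hi = np.minimum(config.mass_bounds[1], config.subject_peak_cap / rel.max(axis=1))
    lo = np.full(n, config.mass_bounds[0])
    hi = np.maximum(hi, lo + 1.0)
    # inverse-CDF truncated normal (exact; no rejection)
    from scipy.special import ndtr, ndtri

    a = ndtr((lo - config.mass_mean) / config.mass_sd)
    b = ndtr((hi - config.mass_mean) / config.mass_sd)
    mass = config.mass_mean + config.mass_sd * ndtri(a + (b - a) * rng.random(n))

    f_subj = rel * mass[:, None]  # subject-level absolute peak force

    # F5ms realized through the peak-force ratio so that light athletes stay
    # geometrically consistent (F5ms < 0.5 * Fpeak) while the per-condition
    # F5ms marginals keep the calibrated mean/SD
    for j in range(k):
        c = config.conditions[conds[j]]
        mu_f, var_f = float(f_subj[:, j].mean()), float(f_subj[:, j].var())
        r_mean = c.mean_f5ms / mu_f
        resid = max(c.sd_f5ms**2 - r_mean**2 * var_f, (0.005 * mu_f * r_mean) ** 2)
        # center the ratio deviation on the already-drawn f5 so the shared
        # intercept structure carries over
        z5 = (f5[:, j] - c.mean_f5ms) / c.sd_f5ms
        r = r_mean + math.sqrt(resid) / mu_f * z5
        f5[:, j] = np.clip(r, 0.05, 0.475) * f_subj[:, j]

    # subject-level impulse must leave room for t_peak > t90 under punch jitter
    area_subj = rise_area_to_t90(f_subj, f5, t50 / 1e3, t90 / 1e3)
    imp = np.maximum(imp, 1.08 * area_subj)

    type_names = [t for t, _ in config.punch_type_mix]
    type_probs = np.array([p for _, p in config.punch_type_mix], dtype=float)
    type_probs /= type_probs.sum()
    scale_map = dict(config.punch_type_scale)
    scales = np.array([scale_map[t] for t in type_names])
    scales = scales / float(scales @ type_probs)  # mixture-mean 1: no net bias

    rows = []
    cv, cvi = config.punch_cv, config.punch_cv_idio
    for si in range(n):
        for j, name in enumerate(conds):
            ti = rng.choice(len(type_names), size=m, p=type_probs)
            tf = scales[ti]

            r5 = f5[si, j] / f_subj[si, j]  # F5ms as a fraction of peak force

            def draw_punches():
                u = rng.standard_normal(m)
                fp = f_subj[si, j] * tf * (1.0 + cv * u + cvi * rng.standard_normal(m))
                ip = imp[si, j] * tf * (1.0 + 0.8 * cv * u + cvi * rng.standard_normal(m))
                f5p = fp * np.clip(r5 * (1.0 + 0.01 * rng.standard_normal(m)), 0.02, 0.485)
                t50p = t50[si, j] + 0.15 * rng.standard_normal(m)
                t90p = t90[si, j] + 0.2 * rng.standard_normal(m)
                return np.stack([fp, ip, f5p, t50p, t90p], axis=1)

            def valid_punches(x):
                fp, ip, f5p, t50p, t90p = x.T
                ok = (
                    (fp > 60.0)
                    & (fp <= config.punch_peak_cap)
                    & (ip > 0.5)
                    & (t50p > 5.25)
                    & (t90p > t50p + 1.0)
                )
                area = rise_area_to_t90(fp, f5p, t50p / 1e3, t90p / 1e3)
                return ok & (ip > area + 1e-4 * fp)

            x = _redraw(draw_punches, valid_punches, what="punch kinetics")
            fp, ip, f5p, t50p, t90p = x.T
            tpk = solve_t_peak(fp, f5p, t50p / 1e3, t90p / 1e3, ip)
            for pi in range(m):
                rows.append(
                    (
                        f"S{si + 1:02d}", name, pi, type_names[ti[pi]],
                        mass[si], z_subj[si], emg_gain[si],
                        fp[pi], f5p[pi], t50p[pi] / 1e3, t90p[pi] / 1e3, tpk[pi],
                        ip[pi], fp[pi] / mass[si],
                    )
                )

    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "condition", "punch_index", "punch_type",
            "body_mass", "subject_effect", "emg_gain",
            "f_peak", "f5ms", "t50", "t90", "t_peak",
            "impulse", "rel_peak_force",
        ],
    )


@dataclass
class CohortRecord:
    emg: Optional[EMGTrace]
    force: ForceTrace
    params_true: PunchPulseParams


@dataclass
class CohortDataset:
    subjects: List[SubjectProfile]
    records: Dict[Tuple[str, str, int], CohortRecord]
    seed: int
    punch_count_per_session: int
    config: CohortConfig
    params_frame: pd.DataFrame

    @property
    def conditions(self) -> List[str]:
        return list(self.config.conditions)


def generate_cohort(
    config: Optional[CohortConfig] = None, seed: int = 0, include_emg: bool = True
) -> CohortDataset:
    """Generate the full paired sEMG/force cohort. Deterministic given seed.

    ``include_emg=False`` skips sEMG synthesis (records carry ``emg=None``)
    for force-only analyses; force traces are identical either way.
    """
    config = config or CohortConfig()
    df = sample_cohort_params(config, seed)

    couplings = {}
    cp = config.coupling
    for name in config.conditions:
        sel = df[df.condition == name]
        col = {
            "relative": sel.rel_peak_force.to_numpy() * cp.reference_mass,
            "absolute": sel.f_peak.to_numpy(),
            "f5ms": sel.f5ms.to_numpy(),
            "impulse": sel.impulse.to_numpy() * cp.impulse_scale,
        }
        vals = np.stack([col[t] for t in cp.channel_targets], axis=1)
        couplings[name] = calibrate_coupling(cp, vals)

    sub_rows = df.drop_duplicates("subject_id").sort_values("subject_id")
    subjects = [
        SubjectProfile(r.subject_id, r.body_mass, r.subject_effect, r.emg_gain)
        for r in sub_rows.itertuples()
    ]
    sub_map = {p.subject_id: p for p in subjects}

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    records: Dict[Tuple[str, str, int], CohortRecord] = {}
    for r in df.itertuples():
        p = PunchPulseParams(
            f_peak=r.f_peak, f5ms=r.f5ms, t50=r.t50, t90=r.t90, t_peak=r.t_peak,
            decay_tau=config.decay_tau, contact_time=config.contact_time,
            punch_type=r.punch_type,
        )
        force = synthesize_force_pulse(p, config.fs)
        emg = None
        if include_emg:
            emg = synthesize_emg(
                p, couplings[r.condition], sub_map[r.subject_id], rng,
                fs=config.fs, window_ms=config.emg_window_ms,
            )
        records[(r.subject_id, r.condition, r.punch_index)] = CohortRecord(emg, force, p)

    return CohortDataset(
        subjects=subjects,
        records=records,
        seed=seed,
        punch_count_per_session=config.punch_count_per_session,
        config=config,
        params_frame=df,
    )
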