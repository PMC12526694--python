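"""Punch detection and kinetic extraction: closed-form and round-trip oracles."""

import math

import numpy as np
import pytest

from punchkan.cohort import PunchPulseParams, synthesize_force_pulse
from punchkan.kinetics import (
    ForceTrace,
    PunchEvent,
    detect_punches,
    extract_parameters,
    summarize_subject,
)


def ramp_trace():
    """0 -> 1000 N linear over 10 ms, instant drop; contact at sample 0."""
    x = np.concatenate([100.0 * np.arange(11), np.zeros(40)])
    return ForceTrace(x, fs=1000.0)


def test_triangle_closed_form_geometry():
    trace = ramp_trace()
    (event,) = detect_punches(trace)
    p = extract_parameters(trace, event, body_mass=50.0)
    assert np.isclose(p.relative_peak_force, 20.0)
    assert np.isclose(p.t_f50, 5.0, atol=1e-9)
    assert np.isclose(p.t_f90, 9.0, atol=1e-9)
    assert np.isclose(p.t_f50_90, 4.0, atol=1e-9)
    assert np.isclose(p.t_500n, 5.0, atol=1e-9)
    assert np.isclose(p.f5ms, 500.0)
    assert np.isclose(p.impulse, 5.0)  # 1/2 * 1000 N * 0.010 s


def test_subthreshold_bump_is_invalid():
    x = np.zeros(200)
    x[50:60] = 40.0
    assert detect_punches(ForceTrace(x)) == []


def test_all_zero_trace_gives_empty_list():
    assert detect_punches(ForceTrace(np.zeros(100))) == []


def test_three_pulses_detected_with_correct_contacts():
    p = PunchPulseParams(f_peak=800.0, f5ms=300.0, t50=0.006, t90=0.012,
                        t_peak=0.015, contact_time=0.0)
    pulse = synthesize_force_pulse(p, 1000.0, duration=0.2).samples
    x = np.zeros(1700)
    contacts = [100, 600, 1100]
    for c in contacts:
        x[c : c + len(pulse)] += pulse
    events = detect_punches(ForceTrace(x))
    assert len(events) == 3
    for ev, c in zip(events, contacts):
        assert abs(ev.contact_index - c) <= 1


def test_low_peak_leaves_t500_undefined():
    x = np.concatenate([np.arange(0, 401, 40.0), np.zeros(30)])
    trace = ForceTrace(x)
    (event,) = detect_punches(trace)
    p = extract_parameters(trace, event, 70.0)
    assert math.isnan(p.t_500n)
    assert np.isfinite(p.t_f50) and np.isfinite(p.impulse)


def test_invalid_event_and_bad_mass_raise():
    trace = ramp_trace()
    bad = PunchEvent(0, 1, 10, valid=False)
    with pytest.raises(ValueError):
        extract_parameters(trace, bad, 50.0)
    (event,) = detect_punches(trace)
    with pytest.raises(ValueError):
        extract_parameters(trace, event, 0.0)


@pytest.mark.parametrize("c", [1.5, 2.0])
def test_scaling_trace_scales_amplitudes_not_threshold_times(c):
    trace = ramp_trace()
    scaled = ForceTrace(c * trace.samples, trace.fs)
    (e1,) = detect_punches(trace)
    (e2,) = detect_punches(scaled)
    p1 = extract_parameters(trace, e1, 60.0)
    p2 = extract_parameters(scaled, e2, 60.0)
    assert np.isclose(p2.relative_peak_force, c * p1.relative_peak_force)
    assert np.isclose(p2.f5ms, c * p1.f5ms, rtol=1e-6)
    assert np.isclose(p2.impulse, c * p1.impulse, rtol=1e-6)
    assert np.isclose(p2.t_f50, p1.t_f50, atol=0.05)
    assert np.isclose(p2.t_f90, p1.t_f90, atol=0.05)


def test_impulse_matches_dense_integration_oracle():
    """Trapezoid impulse equals dense integration of the sampled interpolant."""
    p = PunchPulseParams(f_peak=1500.0, f5ms=600.0, t50=0.0062, t90=0.0118,
                        t_peak=0.0151, contact_time=0.1)
    trace = synthesize_force_pulse(p, 1000.0)
    (event,) = detect_punches(trace)
    got = extract_parameters(trace, event, 68.2).impulse
    # exact check: sampled trapezoid equals an explicit per-interval loop
    x = trace.samples
    c0, pk = event.contact_index - 1, event.peak_index
    loop = sum(0.5 * (x[i] + x[i + 1]) * 1e-3 for i in range(c0, pk))
    assert np.isclose(np.trapezoid(x[c0 : pk + 1], dx=1e-3), loop, rtol=1e-12)
    # dense integration of the interpolant on [contact, t_peak]; the refined
    # peak instant carries a small decay-curvature residual (< 0.5%)
    t = np.arange(len(x)) / trace.fs
    fine = np.linspace(0.1, 0.1 + p.t_peak, 200001)
    dense = np.trapezoid(np.interp(fine, t, x), fine)
    assert np.isclose(got, dense, rtol=5e-3)
    # and both match the drawn target area
    want = (0.5 * 600 * 0.005 + 0.5 * (600 + 750) * 0.0012
            + 0.7 * 1500 * 0.0056 + 0.95 * 1500 * 0.0033)
    assert np.isclose(got, want, rtol=5e-3)


def test_generator_round_trip_within_one_sample(small_cohort):
    """Extraction recovers the drawn anchors to sub-sample accuracy."""
    mass = {s.subject_id: s.body_mass for s in small_cohort.subjects}
    df = small_cohort.params_frame
    for r in df.sample(30, random_state=0).itertuples():
        rec = small_cohort.records[(r.subject_id, r.condition, r.punch_index)]
        (event,) = detect_punches(rec.force)
        kp = extract_parameters(rec.force, event, mass[r.subject_id])
        # peak accurate to one sample period x the local (last-segment) slope
        slope = 0.1 * r.f_peak / (r.t_peak - r.t90)  # N/s near the peak
        peak_bound = max(5.0, slope * 1e-3)
        assert abs(kp.relative_peak_force - r.rel_peak_force) < peak_bound / r.body_mass
        assert abs(kp.t_f50 - r.t50 * 1e3) < 1.0
        assert abs(kp.t_f90 - r.t90 * 1e3) < 1.0
        assert abs(kp.f5ms - r.f5ms) < 0.02 * r.f5ms
        assert abs(kp.impulse - r.impulse) < max(0.25, 1.2e-3 * r.f_peak)
        assert abs(event.contact_index - round(0.1 * 1000)) <= 1


def test_summarize_subject():
    trace = ramp_trace()
    (event,) = detect_punches(trace)
    p1 = extract_parameters(trace, event, 50.0)
    s = summarize_subject([p1])
    assert s.means["impulse"] == p1.impulse and s.n_punches == 1

    p2 = extract_parameters(ForceTrace(2 * trace.samples), event, 50.0)
    s2 = summarize_subject([p1, p2])
    assert np.isclose(s2.means["impulse"], (p1.impulse + p2.impulse) / 2)

    low = ForceTrace(0.4 * trace.samples)
    (e3,) = detect_punches(low)
    p3 = extract_parameters(low, e3, 50.0)
    s3 = summarize_subject([p1, p3])
    assert s3.undefined_counts["t_500n"] == 1  # 400 N peak has no t500N
    assert np.isclose(s3.means["t_500n"], p1.t_500n)

    with pytest.raises(ValueError):
        summarize_subject([])
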