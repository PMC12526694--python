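"""Synthetic cohort generator: closed forms, determinism, structure, coupling."""

import numpy as np
import pytest

from punchkan import cohort as ch
from punchkan.cohort import (
    CohortConfig,
    CouplingSpec,
    PunchPulseParams,
    SubjectProfile,
    calibrate_coupling,
    default_condition_specs,
    generate_cohort,
    rise_area_to_t90,
    sample_cohort_params,
    sample_punch_params,
    solve_t_peak,
    synthesize_emg,
    synthesize_force_pulse,
)


# -- closed-form punch geometry ---------------------------------------------

def test_neutral_lnmes_draw_hits_condition_means(lnmes_spec):
    subj = SubjectProfile("S1", body_mass=68.2, subject_effect=0.0)
    p = sample_punch_params(lnmes_spec, subj, np.random.default_rng(0), jitter=False)
    assert np.isclose(p.f_peak, 28.2 * 68.2)  # 1923.24 N
    assert np.isclose(p.f5ms, 754.0)
    assert np.isclose(p.t50, 0.0062) and np.isclose(p.t90, 0.0118)


def test_t_peak_closed_form_and_integral_cross_check():
    f, f5, t50, t90, imp = 1923.0, 754.0, 0.0062, 0.0118, 0.0166 * 1000
    t_peak = solve_t_peak(f, f5, t50, t90, 16.6)
    # frozen value from the piecewise-linear trapezoid relation
    area = 0.5 * 754 * 0.005 + 0.5 * (754 + 0.5 * f) * 0.0012 + 0.7 * f * 0.0056
    assert np.isclose(t_peak, 0.0118 + (16.6 - area) / (0.95 * f), atol=1e-12)
    assert 0.0145 < t_peak < 0.0155
    # cross-check: dense numeric integral of the synthesized rise equals 16.6
    p = PunchPulseParams(f, f5, t50, t90, t_peak, contact_time=0.0)
    fs_hi = 200000.0
    trace = synthesize_force_pulse(p, fs_hi, duration=t_peak + 0.05)
    n_peak = int(round(t_peak * fs_hi))
    integral = np.trapezoid(trace.samples[: n_peak + 1], dx=1 / fs_hi)
    assert np.isclose(integral, 16.6, rtol=1e-4)


def test_zero_third_segment_is_rejected():
    f, f5, t50, t90 = 1500.0, 500.0, 0.006, 0.012
    boundary = rise_area_to_t90(f, f5, t50, t90)
    with pytest.raises(ValueError):
        solve_t_peak(f, f5, t50, t90, boundary)


def test_sample_punch_params_errors_after_exhausted_redraws(lnmes_spec):
    subj = SubjectProfile("S1", body_mass=1e-3)  # forces f5 >= 0.5*f_peak
    with pytest.raises(ValueError):
        sample_punch_params(lnmes_spec, subj, np.random.default_rng(0))


# -- force pulse ------------------------------------------------------------

def test_pulse_passes_through_anchors():
    p = PunchPulseParams(1000.0, 300.0, 0.006, 0.009, 0.0105, contact_time=0.1)
    trace = synthesize_force_pulse(p, 1000.0)
    x = trace.samples
    assert x[100] == 0.0 and np.all(x[:100] == 0.0)
    assert np.isclose(x[105], 300.0)  # F5ms anchor
    assert np.isclose(x[106], 500.0)  # t50 anchor
    assert np.isclose(x[109], 900.0)  # t90 anchor
    # peak sample within one interpolation step of f_peak (local slope x dt)
    assert 1000.0 - 70.0 < x.max() <= 1000.0


def test_zero_force_pulse_is_all_zero():
    p = PunchPulseParams(0.0, 0.0, 0.006, 0.009, 0.0105)
    assert np.all(synthesize_force_pulse(p, 1000.0, duration=0.3).samples == 0.0)


def test_pulse_rejects_out_of_range_peak():
    with pytest.raises(ValueError):
        PunchPulseParams(2100.0, 700.0, 0.006, 0.012, 0.015)


# -- sEMG -------------------------------------------------------------------

def test_emg_zero_amplitude_gives_zero_channels():
    cp = calibrate_coupling(CouplingSpec(), np.zeros((0, 4)))
    p = PunchPulseParams(0.0, 0.0, 0.006, 0.009, 0.0105)
    subj = SubjectProfile("S1", 68.2)
    emg = synthesize_emg(p, cp, subj, np.random.default_rng(0))
    assert emg.samples.shape == (300, 4)
    assert np.all(emg.samples == 0.0)


def test_emg_noise_free_amplitude_is_deterministic_in_kinetics():
    cp = CouplingSpec(noise_share=0.0)
    p = PunchPulseParams(1500.0, 600.0, 0.0062, 0.0118, 0.015)
    subj = SubjectProfile("S1", 68.2)
    e1 = synthesize_emg(p, cp, subj, np.random.default_rng(1))
    e2 = synthesize_emg(p, cp, subj, np.random.default_rng(2))
    # carriers differ, but the encoded burst amplitudes are identical
    assert np.allclose(e1.meta["burst_amplitudes"], e2.meta["burst_amplitudes"])


def test_uncalibrated_noisy_coupling_raises():
    p = PunchPulseParams(1500.0, 600.0, 0.0062, 0.0118, 0.015)
    with pytest.raises(ValueError, match="calibrated"):
        synthesize_emg(p, CouplingSpec(), SubjectProfile("S1", 68.2),
                       np.random.default_rng(0))


def test_noise_share_sets_variance_split():
    """Monte Carlo: corr^2(encoded value, true value) ~ 1 - noise_share per channel."""
    cfg = CohortConfig(
        conditions={"L-NMES": default_condition_specs()["L-NMES"]},
        n_subjects=16, punch_count_per_session=126,
    )
    ds = generate_cohort(cfg, 3)
    vt = np.array([r.emg.meta["true_values"] for r in ds.records.values()])
    ve = np.array([r.emg.meta["encoded_values"] for r in ds.records.values()])
    assert len(vt) >= 2000
    for c in range(4):
        r2 = np.corrcoef(vt[:, c], ve[:, c])[0, 1] ** 2
        assert abs(r2 - 0.75) < 0.03, (c, r2)


# -- cohort structure -------------------------------------------------------

def test_cohort_determinism_bit_identical():
    cfg = CohortConfig(n_subjects=3, punch_count_per_session=4)
    a = generate_cohort(cfg, 42)
    b = generate_cohort(cfg, 42)
    assert a.params_frame.equals(b.params_frame)
    for key in a.records:
        assert np.array_equal(a.records[key].emg.samples, b.records[key].emg.samples)
        assert np.array_equal(a.records[key].force.samples, b.records[key].force.samples)
    c = generate_cohort(cfg, 43)
    assert not a.params_frame.equals(c.params_frame)


def test_cohort_record_count_is_product(small_cohort):
    cfg = small_cohort.config
    assert len(small_cohort.records) == cfg.n_subjects * len(cfg.conditions) * cfg.punch_count_per_session


def test_full_cohort_would_have_11340_records():
    cfg = CohortConfig()
    df = sample_cohort_params(cfg, 0)
    assert len(df) == 30 * 3 * 126 == 11340


def test_subject_intercepts_create_positive_icc():
    """Variance decomposition of per-subject condition means: the shared
    athlete intercept must induce between-condition correlation."""
    df = sample_cohort_params(CohortConfig(punch_count_per_session=20), 5)
    sub = df.groupby(["subject_id", "condition"]).rel_peak_force.mean().unstack()
    x = sub.to_numpy()
    cors = np.corrcoef(x, rowvar=False)
    off_diag = cors[np.triu_indices_from(cors, 1)]
    assert np.all(off_diag > 0.2)


def test_subject_masses_respect_sensor_headroom(small_cohort):
    df = small_cohort.params_frame
    assert df.f_peak.max() <= 1995.0 + 1e-9
    assert (df.body_mass > 0).all()


def test_condition_calibration_parameter_level():
    """Per-condition means of the three force indicators within 2 SEM of the
    calibration cells (fixed seed, n = 30)."""
    df = sample_cohort_params(CohortConfig(), 42)
    cells = {
        "Sham": dict(rel=(22.7, 5.5), impulse=(11.3, 1.2), f5ms=(511, 77)),
        "U-NMES": dict(rel=(24.5, 4.7), impulse=(13.2, 0.9), f5ms=(631, 89)),
        "L-NMES": dict(rel=(28.2, 3.2), impulse=(16.6, 2.3), f5ms=(754, 94)),
    }
    col = {"rel": "rel_peak_force", "impulse": "impulse", "f5ms": "f5ms"}
    for cond, targets in cells.items():
        sub = df[df.condition == cond].groupby("subject_id")[list(col.values())].mean()
        for key, (mean, sd) in targets.items():
            got = sub[col[key]].mean()
            assert abs(got - mean) < 2 * sd / np.sqrt(30), (cond, key, got)
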