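"""Windowing, metrics, loss, optimizer behavior, baseline architectures."""

import numpy as np
import pytest

from punchkan import pipeline
from punchkan.autograd import Tensor
from punchkan.training import (
    Adam,
    BaselineSpec,
    LSTMRegressor,
    RNNRegressor,
    TrainingConfig,
    build_baseline,
    build_model,
    compute_metrics,
    evaluate,
    fit_indicator,
    loss,
    subject_split,
    train,
)


# -- metrics ----------------------------------------------------------------

def test_metrics_perfect_prediction():
    m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (m.rmse, m.mae, m.r2) == (0.0, 0.0, 1.0)


def test_metrics_mean_predictor_has_zero_r2():
    y = np.array([1.0, 2.0, 3.0, 6.0])
    m = compute_metrics(y, np.full(4, y.mean()))
    assert np.isclose(m.r2, 0.0)


def test_metrics_hand_computed_example():
    m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
    assert np.isclose(m.rmse, np.sqrt(1 / 3))
    assert np.isclose(m.mae, 1 / 3)
    assert np.isclose(m.r2, 0.5)


def test_metrics_match_direct_formulas_on_random_vectors(rng):
    for _ in range(20):
        y = rng.normal(size=50)
        yh = y + rng.normal(size=50)
        m = compute_metrics(y, yh)
        assert np.isclose(m.rmse, np.sqrt(np.mean((y - yh) ** 2)))
        assert np.isclose(m.mae, np.mean(np.abs(y - yh)))
        assert np.isclose(m.r2, 1 - np.sum((y - yh) ** 2) / np.sum((y - y.mean()) ** 2))
        assert m.rmse >= m.mae >= 0.0


def test_metrics_zero_variance_target_is_an_error():
    with pytest.raises(ValueError):
        compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


# -- loss -------------------------------------------------------------------

def test_loss_examples():
    assert loss([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert loss([1.0], [1.0], params=[np.array([2.0])], l2_lambda=1.0) == 4.0
    assert np.isclose(loss([1.0, 2.0, 4.0], [1.0, 2.0, 3.0]), 1 / 3)


# -- windows & splits -------------------------------------------------------

def test_make_windows_counts_and_shapes(small_cohort, small_envelopes, small_kinetics):
    w = pipeline.windows_for(small_cohort, small_envelopes, small_kinetics,
                             "relative_peak_force", "L-NMES")
    assert w.X.shape == (6 * 8, 30, 4)  # 300 ms envelope decimated by 10
    assert len(w.y) == len(w.subjects) == 48


def test_make_windows_drops_undefined_t500(small_cohort, small_envelopes, small_kinetics):
    w = pipeline.windows_for(small_cohort, small_envelopes, small_kinetics,
                             "t_500n", "Sham")
    assert len(w.y) + w.n_dropped == 48
    assert np.isfinite(w.y).all()


@pytest.mark.parametrize("seed", range(10))
def test_subject_split_is_leak_free_for_every_seed(seed):
    subjects = np.repeat([f"S{i}" for i in range(30)], 7)
    tr, te = subject_split(subjects, 0.8, seed)
    assert len(np.unique(subjects[tr])) == 24
    assert len(np.unique(subjects[te])) == 6
    assert not set(subjects[tr]) & set(subjects[te])


# -- optimizer & loop -------------------------------------------------------

def test_huge_l2_shrinks_parameters_toward_zero(rng):
    """Penalty-dominated limit; Adam's normalized steps shrink weights by
    ~lr per step, so the norm decays monotonically to near zero."""
    X = rng.normal(size=(64, 8, 2))
    y = rng.normal(size=64)
    model = build_model("kan", 2, 8, seed=0)
    norms = [sum(float(np.sum(p.data**2)) for p in model.parameters())]
    cfg = TrainingConfig(epochs=100, batch_size=16, l2_lambda=1e4, seed=0)
    for _ in range(4):
        train(model, X, y, cfg)
        norms.append(sum(float(np.sum(p.data**2)) for p in model.parameters()))
    assert all(b < a for a, b in zip(norms, norms[1:]))
    assert norms[-1] < 1e-2 * norms[0]


def test_training_is_deterministic_given_seed(rng):
    X = rng.normal(size=(100, 8, 2))
    y = rng.normal(size=100)
    hists = []
    for _ in range(2):
        model = build_model("kan", 2, 8, seed=7)
        _, h = train(model, X, y, TrainingConfig(epochs=5, seed=7))
        hists.append(h["train_loss"])
    assert hists[0] == hists[1]


def test_noise_free_coupling_trains_to_the_carrier_noise_floor():
    """With noise_share = 0 the burst amplitude determines the target, but a
    single 300 ms stochastic carrier window estimates that amplitude with a
    few percent of error; the oracle floor is the RMSE of the exact
    generative inverse applied to the extracted envelope. A trained KAN must
    approach that floor (and sit far below the target SD)."""
    from punchkan import cohort as ch
    from punchkan.preprocessing import moving_mean

    cfg = ch.CohortConfig(
        conditions={"L-NMES": ch.default_condition_specs()["L-NMES"]},
        coupling=ch.CouplingSpec(noise_share=0.0),
        n_subjects=8, punch_count_per_session=20, emg_gain_cv=0.0,
    )
    ds = ch.generate_cohort(cfg, 9)
    env = pipeline.preprocess_cohort(ds)
    kdf = pipeline.extract_kinetics(ds)
    w = pipeline.windows_for(ds, env, kdf, "relative_peak_force", "L-NMES")

    # oracle: invert channel 0's envelope peak through the true burst shape
    cp = cfg.coupling
    n = 300
    t = np.arange(n)
    start, width = int(0.2 * n), int(0.733 * n)
    burst = np.zeros(n)
    inside = (t >= start) & (t < start + width)
    burst[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - start) / width))
    burst_peak = moving_mean(burst[:, None], 50).max()
    valid = kdf[(kdf.condition == "L-NMES") & kdf.valid]
    keys = list(zip(valid.subject_id, valid.condition, valid.punch_index))
    est_amp = np.array(
        [env[k][:, 0].max() for k in keys]
    ) / (cp.channel_weights[0] * np.sqrt(2 / np.pi) * burst_peak)
    y_hat = cp.activation(est_amp) / cp.reference_mass
    floor = np.sqrt(np.mean((y_hat - valid.relative_peak_force.to_numpy()) ** 2))

    res = fit_indicator(w, "kan", TrainingConfig(epochs=150, seed=0, split=0.99))
    assert res["train_metrics"].rmse < max(1.5 * floor, 0.1 * np.std(w.y))
    assert res["train_metrics"].rmse < 0.25 * np.std(w.y)


def test_divergence_aborts_with_diagnostics(rng):
    X = rng.normal(size=(32, 8, 2))
    y = rng.normal(size=32)
    model = build_model("kan", 2, 8, seed=0)
    with pytest.raises(RuntimeError, match="diverged"):
        train(model, X, y * 1e150, TrainingConfig(epochs=3, seed=0, learning_rate=1e100))


# -- baselines --------------------------------------------------------------

def test_rnn_spec_single_128_unit_tanh_layer():
    model = build_baseline(BaselineSpec("rnn"), n_channels=4, window_len=10)
    assert isinstance(model, RNNRegressor)
    assert model.w_hh.data.shape == (128, 128)
    assert model.w_ih.data.shape == (4, 128)
    assert model.dropout == 0.2


def test_lstm_spec_two_128_unit_layers():
    model = build_baseline(BaselineSpec("lstm"), n_channels=4, window_len=10)
    assert isinstance(model, LSTMRegressor)
    assert len(model.layers) == 2
    for w_ih, w_hh, b in model.layers:
        assert w_hh.data.shape == (128, 4 * 128)
        assert b.data.shape == (512,)


def test_dropout_disabled_at_evaluation_is_deterministic(rng):
    model = build_baseline(BaselineSpec("lstm", hidden_units=8), 2, 6, seed=0)
    x = rng.normal(size=(3, 6, 2))
    assert np.array_equal(model.predict(x), model.predict(x))


def test_dropout_active_in_training_mode(rng):
    model = build_baseline(BaselineSpec("rnn", hidden_units=16), 2, 6, seed=0)
    x = rng.normal(size=(4, 6, 2))
    a = model.forward(x, train=True, rng=np.random.default_rng(0)).data
    b = model.forward(x, train=True, rng=np.random.default_rng(1)).data
    assert not np.array_equal(a, b)


def test_invalid_baseline_kind_rejected():
    with pytest.raises(ValueError):
        BaselineSpec("gru")
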