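"""Windowing, normalization and the recurrent foot-flat classifier."""

import numpy as np
import pandas as pd
import pytest

from solestep.footflat_model import (
    FootFlatClassifier,
    ModelConfig,
    WindowNormalizer,
    apply_normalizer,
    build_model,
    fit_normalizer,
    make_windows,
    predict_status,
    train,
    window_samples,
)
from solestep.recording_io import EnrichedRecording


def _enriched(n=100, statuses=None, fs=200.0):
    rng = np.random.default_rng(0)
    frame = pd.DataFrame({
        "time_s": np.arange(n) / fs,
        "acc_x": rng.normal(0, 1, n), "acc_y": rng.normal(0, 1, n),
        "acc_z": rng.normal(1, 0.2, n),
        "gyro_x": rng.normal(0, 50, n), "gyro_y": rng.normal(0, 50, n),
        "gyro_z": rng.normal(0, 50, n),
    })
    frame["acc_norm"] = np.linalg.norm(frame[["acc_x", "acc_y", "acc_z"]], axis=1)
    frame["gyro_norm"] = np.linalg.norm(frame[["gyro_x", "gyro_y", "gyro_z"]], axis=1)
    frame["foot_status"] = (statuses if statuses is not None
                            else rng.integers(0, 2, n))
    frame["activity"] = 0
    return EnrichedRecording(frame, fs=fs)


class TestMakeWindows:
    def test_window_count_without_exclusions(self):
        enr = _enriched(100, statuses=np.zeros(100, dtype=int))
        ds = make_windows(enr, ["gyro_norm"], window_ms=125.0, stride=1)
        assert ds.window_samples == 25          # 0.125 s × 200 Hz
        assert len(ds) == 76                    # N − w + 1

    def test_strided_window_count(self):
        enr = _enriched(100, statuses=np.zeros(100, dtype=int))
        ds = make_windows(enr, ["gyro_norm"], window_ms=125.0, stride=4)
        assert len(ds) == 19                    # floor(75/4) + 1

    def test_undetermined_endpoints_excluded(self):
        statuses = np.zeros(100, dtype=int)
        statuses[50:60] = 2
        enr = _enriched(100, statuses=statuses)
        ds = make_windows(enr, ["gyro_norm"], 125.0, stride=1)
        assert len(ds) == 76 - 10
        assert set(np.unique(ds.y)) <= {0, 1}

    def test_window_longer_than_recording_raises(self):
        enr = _enriched(10)
        with pytest.raises(ValueError):
            make_windows(enr, ["gyro_norm"], 125.0)

    def test_window_label_is_final_sample_status(self):
        statuses = np.zeros(50, dtype=int)
        statuses[30] = 1
        enr = _enriched(50, statuses=statuses)
        ds = make_windows(enr, ["acc_norm"], 50.0, stride=1)  # w = 10
        flat_ends = np.flatnonzero(ds.y == 1)
        assert flat_ends.size == 1
        assert ds.end_times[flat_ends[0]] == pytest.approx(30 / 200.0)


class TestWindowNormalizer:
    def test_train_stats_zero_mean_unit_sd(self, rng):
        X = rng.normal(3.0, 2.0, size=(500, 10, 2)).astype(np.float32)
        norm = WindowNormalizer().fit(X)
        Xn = norm.transform(X)
        np.testing.assert_allclose(Xn.mean(axis=(0, 1)), 0.0, atol=1e-5)
        np.testing.assert_allclose(Xn.std(axis=(0, 1)), 1.0, atol=1e-5)

    def test_constant_channel_clamped(self, rng):
        X = np.ones((50, 5, 1), dtype=np.float32)
        with pytest.warns(UserWarning):
            norm = WindowNormalizer().fit(X)
        assert norm.scale_[0] == 1.0
        assert np.all(norm.transform(X) == 0.0)

    def test_heldout_uses_train_stats(self, rng):
        train_X = rng.normal(0, 1, size=(200, 8, 1)).astype(np.float32)
        test_X = rng.normal(5, 1, size=(200, 8, 1)).astype(np.float32)
        norm = WindowNormalizer().fit(train_X)
        out = norm.transform(test_X)
        assert out.mean() > 3.0  # not re-centered on its own stats


def lstm_layer_params(u, c):
    """Closed-form parameter tally: 4·(u·(c+u)+u)."""
    return 4 * (u * (c + u) + u)


class TestBuildModel:
    def test_parameter_count_matches_analytic_tally(self):
        cfg = ModelConfig()  # 32 units, 2 layers, no dense
        model = build_model(cfg, n_channels=3)
        expected = (lstm_layer_params(32, 3) + lstm_layer_params(32, 32)
                    + 32 + 1)  # output weights + bias
        assert model.n_parameters_ == expected

    def test_parameter_count_with_dense(self):
        cfg = ModelConfig(n_lstm_units=16, n_lstm_layers=1,
                          dense_layer_active=True, n_dense_units=8)
        model = build_model(cfg, n_channels=2)
        expected = lstm_layer_params(16, 2) + (16 * 8 + 8) + (8 + 1)
        assert model.n_parameters_ == expected

    def test_single_layer_structure(self):
        model = build_model(ModelConfig(n_lstm_layers=1), 3)
        assert "Wx0" in model.net_.params and "Wx1" not in model.net_.params
        assert "Wd" not in model.net_.params

    def test_invalid_activation_rejected(self):
        with pytest.raises(ValueError, match="activation"):
            build_model(ModelConfig(lstm_activation="gelu"), 3)


def _toy_dataset(n=3000, w=10, seed=0):
    """Separable toy: label 1 iff the first channel's window mean < 0.1."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.5, 0.5, size=(n, w, 2)).astype(np.float32)
    shift = rng.random(n) < 0.5
    X[shift, :, 0] -= 0.6
    y = (X[:, :, 0].mean(axis=1) < 0.1).astype(np.int8)
    return X, y


class TestTraining:
    def test_separable_toy_high_accuracy(self):
        X, y = _toy_dataset()
        clf = FootFlatClassifier(n_lstm_units=8, n_lstm_layers=1, dropout=0.0,
                                 batch_size=256, learning_rate=1e-2,
                                 epochs=15, random_state=0)
        clf.fit(X[:2400], y[:2400], validation_data=(X[2400:], y[2400:]))
        acc = (clf.predict(X[2400:]) == y[2400:]).mean()
        assert acc > 0.99
        # oracle check: predictions agree with the defining threshold rule
        oracle = (X[2400:, :, 0].mean(axis=1) < 0.1).astype(np.int8)
        assert (clf.predict(X[2400:]) == oracle).mean() > 0.99

    def test_patience_stops_training(self):
        X, y = _toy_dataset(600)
        # lr=0 never improves after epoch 1 → patience triggers
        clf = FootFlatClassifier(n_lstm_units=4, n_lstm_layers=1, dropout=0.0,
                                 batch_size=128, learning_rate=0.0,
                                 epochs=100, patience=3, random_state=0)
        clf.fit(X, y, validation_data=(X[:100], y[:100]))
        assert clf.history_["stop_reason"] == "patience"
        assert len(clf.history_["loss"]) == 4  # best at epoch 0 + 3 stale epochs

    def test_reproducible_given_seed(self):
        X, y = _toy_dataset(800)
        losses = []
        for _ in range(2):
            clf = FootFlatClassifier(n_lstm_units=4, n_lstm_layers=1,
                                     batch_size=128, epochs=3, random_state=7)
            clf.fit(X, y)
            losses.append(clf.history_["loss"][-1])
        assert losses[0] == losses[1]

    def test_best_checkpoint_loss_non_increasing(self):
        X, y = _toy_dataset(1000)
        clf = FootFlatClassifier(n_lstm_units=6, n_lstm_layers=1, dropout=0.0,
                                 batch_size=128, epochs=8, random_state=1)
        clf.fit(X, y, validation_data=(X[:200], y[:200]))
        running_best = np.minimum.accumulate(clf.history_["val_loss"])
        assert np.all(np.diff(running_best) <= 0)

    def test_empty_dataset_rejected(self):
        clf = FootFlatClassifier()
        with pytest.raises(ValueError):
            clf.fit(np.empty((0, 5, 2), dtype=np.float32), np.empty(0))


class TestPredict:
    def test_probabilities_bounded_for_arbitrary_inputs(self, rng):
        clf = FootFlatClassifier(n_lstm_units=4, n_lstm_layers=1, epochs=1,
                                 batch_size=64, random_state=0)
        X, y = _toy_dataset(200)
        clf.fit(X, y)
        wild = (rng.normal(0, 100, size=(50, 10, 2))).astype(np.float32)
        p = clf.predict_proba(wild)[:, 1]
        assert np.all((p >= 0) & (p <= 1)) and np.all(np.isfinite(p))

    def test_threshold_boundary_is_inclusive(self):
        X, y = _toy_dataset(300)
        clf = FootFlatClassifier(n_lstm_units=4, n_lstm_layers=1, epochs=2,
                                 batch_size=64, random_state=0)
        clf.fit(X, y)
        p = clf.predict_proba(X[:50])[:, 1]
        manual = (p >= 0.5).astype(np.int8)
        np.testing.assert_array_equal(clf.predict(X[:50]), manual)
        clf.set_params(decision_threshold=1.0)
        assert clf.predict(X[:50]).sum() == (p >= 1.0).sum()

    def test_channel_mismatch_rejected(self):
        X, y = _toy_dataset(200)
        clf = FootFlatClassifier(n_lstm_units=4, n_lstm_layers=1, epochs=1,
                                 batch_size=64, random_state=0)
        clf.fit(X, y)
        with pytest.raises(ValueError, match="channel"):
            clf.predict(np.zeros((5, 10, 3), dtype=np.float32))


class TestCheckpointing:
    def test_save_load_round_trip(self, tmp_path):
        X, y = _toy_dataset(400)
        clf = FootFlatClassifier(n_lstm_units=4, n_lstm_layers=1, epochs=2,
                                 batch_size=128, random_state=0)
        clf.fit(X, y)
        path = tmp_path / "model.npz"
        clf.save(path)
        back = FootFlatClassifier.load(path)
        np.testing.assert_array_equal(back.predict_proba(X[:50]),
                                      clf.predict_proba(X[:50]))
        assert back.get_params()["n_lstm_units"] == 4
        assert back.n_parameters_ == clf.n_parameters_


class TestModuleWrappers:
    def test_train_and_predict_status_on_windows(self):
        statuses = (np.arange(300) // 30) % 2
        enr = _enriched(300, statuses=statuses)
        ds = make_windows(enr, ["gyro_norm", "acc_norm"], 50.0)
        norm = fit_normalizer(ds)
        dsn = apply_normalizer(ds, norm)
        model = build_model(ModelConfig(n_lstm_units=4, n_lstm_layers=1,
                                        batch_size=64, input_window_ms=50.0), 2)
        train(model, dsn, dsn, epochs=2)
        stream = predict_status(model, dsn)
        assert stream.shape == dsn.y.shape
        assert set(np.unique(stream)) <= {0, 1}

    def test_window_samples_rounding(self):
        assert window_samples(125.0, 200.0) == 25
        with pytest.raises(ValueError):
            window_samples(1.0, 200.0)
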