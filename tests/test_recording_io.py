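"""Recording I/O: round trips, validation, synchronization, fusion."""

import numpy as np
import pandas as pd
import pytest

from solestep.recording_io import (
    AnnotationTable,
    EnrichedRecording,
    FormatError,
    ImuRecording,
    SyncError,
    align_annotations,
    compute_norms,
    detect_sync_strikes,
    drop_undetermined,
    read_imu_csv,
    rebase,
    write_imu_csv,
)


def _imu_frame(n=100, fs=200.0, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "time_s": np.arange(n) / fs,
        "acc_x": rng.normal(0, 1, n), "acc_y": rng.normal(0, 1, n),
        "acc_z": rng.normal(1, 1, n),
        "gyro_x": rng.normal(0, 100, n), "gyro_y": rng.normal(0, 100, n),
        "gyro_z": rng.normal(0, 100, n),
    })


class TestImuCsvRoundTrip:
    def test_round_trip_preserves_values(self, tmp_path):
        rec = ImuRecording(_imu_frame(1000))
        path = tmp_path / "imu.csv"
        write_imu_csv(rec, path)
        back = read_imu_csv(path)
        np.testing.assert_allclose(back.frame.to_numpy(),
                                   rec.frame.to_numpy(), atol=1e-6)

    def test_out_of_range_gyro_rejected(self, tmp_path):
        frame = _imu_frame(50)
        frame.loc[10, "gyro_y"] = 3000.0
        frame.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(FormatError, match="gyro_y"):
            read_imu_csv(tmp_path / "bad.csv")

    def test_non_monotone_time_rejected(self, tmp_path):
        frame = _imu_frame(50)
        frame["time_s"] = frame["time_s"].sample(frac=1, random_state=0).to_numpy()
        frame.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(FormatError, match="time"):
            read_imu_csv(tmp_path / "bad.csv")

    def test_missing_column_rejected(self, tmp_path):
        frame = _imu_frame(50).drop(columns=["acc_z"])
        frame.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(FormatError, match="acc_z"):
            read_imu_csv(tmp_path / "bad.csv")


class TestComputeNorms:
    def test_known_triples(self):
        frame = _imu_frame(2)
        frame.loc[0, ["acc_x", "acc_y", "acc_z"]] = [3.0, 4.0, 0.0]
        frame.loc[1, ["acc_x", "acc_y", "acc_z"]] = [0.0, 0.0, 0.0]
        rec = compute_norms(ImuRecording(frame))
        assert rec.frame["acc_norm"].iloc[0] == pytest.approx(5.0)
        assert rec.frame["acc_norm"].iloc[1] == 0.0

    def test_random_triples_match_elementwise_oracle(self, rng):
        frame = _imu_frame(100, rng=rng)
        rec = compute_norms(ImuRecording(frame))
        for cols, norm_col in ((["acc_x", "acc_y", "acc_z"], "acc_norm"),
                               (["gyro_x", "gyro_y", "gyro_z"], "gyro_norm")):
            vals = frame[cols].to_numpy()
            # independent elementwise square/sum/sqrt oracle
            oracle = np.sqrt(vals[:, 0]**2 + vals[:, 1]**2 + vals[:, 2]**2)
            np.testing.assert_allclose(rec.frame[norm_col].to_numpy(), oracle,
                                       atol=1e-12)


def _spiked_recording(spike_times, fs=200.0, duration=4.0, amp=5.0):
    n = int(duration * fs)
    frame = _imu_frame(n, fs, rng=np.random.default_rng(1))
    frame[["acc_x", "acc_y", "acc_z"]] = 0.0
    frame["acc_z"] = 1.0
    for t in spike_times:
        frame.loc[int(t * fs), "acc_z"] = amp
    return compute_norms(ImuRecording(frame))


class TestDetectSyncStrikes:
    def test_third_spike_is_t0(self):
        rec = _spiked_recording([1.0, 2.0, 3.0])
        assert detect_sync_strikes(rec) == pytest.approx(3.0, abs=0.01)

    def test_two_spikes_raise(self):
        rec = _spiked_recording([1.0, 2.0])
        with pytest.raises(SyncError):
            detect_sync_strikes(rec)

    def test_close_spikes_merged_into_first(self):
        rec = _spiked_recording([1.0, 1.02, 2.0, 3.0])
        t0 = detect_sync_strikes(rec, min_separation_ms=200)
        assert t0 == pytest.approx(3.0, abs=0.01)

    def test_rebase_shifts_time(self):
        rec = _spiked_recording([1.0, 2.0, 3.0])
        shifted = rebase(rec, 3.0)
        assert shifted.frame["time_s"].iloc[0] == pytest.approx(-3.0)


class TestAlignAnnotations:
    def test_sample_and_hold_run_lengths(self):
        fs, fps = 200.0, 60.0
        rec = compute_norms(ImuRecording(_imu_frame(int(fs), fs)))
        n_frames = 60
        ann = AnnotationTable(pd.DataFrame({
            "time_s": np.arange(n_frames) / fps,
            "foot_status": np.arange(n_frames) % 2,
            "activity": np.zeros(n_frames, dtype=int),
        }))
        enr = align_annotations(rec, ann)
        status = enr.frame["foot_status"].to_numpy()
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate([[2], status, [2]]))))
        assert set(runs.tolist()) <= {3, 4}  # 200/60 ≈ 3.33 samples per frame

    def test_single_frame_constant_status(self):
        rec = compute_norms(ImuRecording(_imu_frame(100)))
        ann = AnnotationTable(pd.DataFrame(
            {"time_s": [0.0], "foot_status": [1], "activity": [0]}))
        enr = align_annotations(rec, ann)
        assert (enr.frame["foot_status"] == 1).all()

    def test_sample_at_frame_time_takes_that_frame(self):
        fs = 200.0
        rec = compute_norms(ImuRecording(_imu_frame(3, fs)))
        ann = AnnotationTable(pd.DataFrame({
            "time_s": [0.0, 1 / fs], "foot_status": [0, 1], "activity": [0, 0]}))
        enr = align_annotations(rec, ann)
        assert enr.frame["foot_status"].tolist() == [0, 1]

    def test_samples_outside_span_dropped(self):
        rec = compute_norms(ImuRecording(_imu_frame(200)))
        ann = AnnotationTable(pd.DataFrame({
            "time_s": [0.1, 0.5], "foot_status": [1, 0], "activity": [0, 0]}))
        enr = align_annotations(rec, ann)
        t = enr.frame["time_s"].to_numpy()
        assert t.min() >= 0.1 and t.max() <= 0.5

    def test_eleven_columns(self, mini_subject):
        rec, ann, _ = mini_subject
        enr = align_annotations(rebase(rec, detect_sync_strikes(rec)), ann)
        assert enr.frame.shape[1] == 11

    def test_empty_annotation_raises(self):
        rec = compute_norms(ImuRecording(_imu_frame(10)))
        ann = AnnotationTable(pd.DataFrame(
            {"time_s": [], "foot_status": [], "activity": []}))
        with pytest.raises(ValueError):
            align_annotations(rec, ann)


class TestDropUndetermined:
    def _enriched(self, statuses):
        n = len(statuses)
        frame = compute_norms(ImuRecording(_imu_frame(n))).frame
        frame["foot_status"] = statuses
        frame["activity"] = 0
        return EnrichedRecording(frame)

    def test_drops_only_status_two(self):
        enr = self._enriched([0, 1, 2, 1])
        out = drop_undetermined(enr)
        assert len(out) == 3
        assert 2 not in out.frame["foot_status"].tolist()

    def test_identity_without_undetermined(self):
        enr = self._enriched([0, 1, 0, 1])
        assert len(drop_undetermined(enr)) == 4

    def test_all_undetermined_warns_and_empties(self):
        enr = self._enriched([2, 2, 2])
        with pytest.warns(UserWarning):
            out = drop_undetermined(enr)
        assert len(out) == 0
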