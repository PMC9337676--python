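import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcgkit.errors import InputError, StateError
from bcgkit.io import AnnotationTrack, Recording
from bcgkit.peaks import (
    PeakModel,
    StoppingCriteria,
    TrainingWindow,
    baseline_peak_detect,
    extract_candidates,
    make_training_windows,
    predict_r_peaks,
    train_peak_model,
)
from bcgkit.preprocess import bandpass
from bcgkit.simulate import AorticParams, BridgeParams, ChannelLayout, beat_force_waveform, synth_bcg

FS = 200.0


def _brute_force_maxima(x):
    """Neighbor-comparison scan (independent oracle for plateau-free signals)."""
    return [i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]


class TestExtractCandidates:
    def test_single_peak(self):
        cands = extract_candidates(
            np.array([0.0, 1.0, 0.0]), FS, min_spacing=0.0, prominence_factor=0.0
        )
        assert [c.sample for c in cands] == [1]
        assert cands[0].kind == "max"

    def test_monotone_ramp_has_no_extrema(self):
        assert extract_candidates(np.arange(100.0), FS) == []

    def test_sine_maxima_count(self):
        t = np.arange(int(5 * FS)) / FS
        x = np.sin(2 * np.pi * 1.2 * t)
        cands = extract_candidates(x, FS, min_spacing=0.3)
        assert len(cands) == 6

    def test_short_signal_rejected(self):
        with pytest.raises(InputError):
            extract_candidates(np.array([1.0, 2.0]), FS)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=200))
    def test_matches_brute_force_scan(self, values):
        x = np.asarray(values)
        # restrict to plateau-free signals
        if np.any(np.diff(x) == 0):
            x = x + np.linspace(0, 1e-9, x.size)
        got = [
            c.sample
            for c in extract_candidates(x, FS, min_spacing=0.0, prominence_factor=0.0)
        ]
        assert got == _brute_force_maxima(x)

    def test_min_spacing_keeps_more_prominent(self):
        x = np.zeros(300)
        x[100] = 1.0
        x[110] = 2.0  # 0.05 s apart at 200 Hz
        cands = extract_candidates(x, FS, min_spacing=0.3, prominence_factor=0.0)
        assert [c.sample for c in cands] == [110]


class TestMakeTrainingWindows:
    def test_target_offset_definition(self):
        # candidate at 5.0 s, nearest truth at 5.2 s -> target +0.2
        fs = 200.0
        x = np.zeros(int(10 * fs))
        x[int(5.0 * fs)] = 1.0
        rec = Recording(x[None, :], fs=fs)
        truth = AnnotationTrack([5.2])
        wins = make_training_windows(rec, truth, prominence_factor=0.0)
        assert len(wins) == 1
        assert wins[0].target_offset == pytest.approx(0.2)

    def test_boundary_window_discarded(self):
        fs = 200.0
        x = np.zeros(int(3 * fs))
        x[int(1.0 * fs)] = 1.0  # 3-s window around t=1 would overrun
        rec = Recording(x[None, :], fs=fs)
        wins = make_training_windows(rec, AnnotationTrack([1.0]), prominence_factor=0.0)
        assert wins == []

    def test_j_centered_targets_near_latency(self, clean_filtered, clean_truth, clean_pair):
        wins = make_training_windows(clean_filtered, clean_truth)
        offsets = np.array([w.target_offset for w in wins])
        # J-peak candidates form a cluster at -latency
        j_cluster = offsets[np.abs(offsets + 0.25) < 0.05]
        assert j_cluster.size >= clean_pair.true_j_times.size - 4
        np.testing.assert_allclose(j_cluster, -0.25, atol=0.02)

    def test_windows_are_zscored(self, clean_filtered, clean_truth):
        wins = make_training_windows(clean_filtered, clean_truth)
        w = wins[0].samples
        assert w.mean() == pytest.approx(0.0, abs=1e-9)
        assert w.std() == pytest.approx(1.0, abs=1e-9)

    def test_no_truth_gives_empty(self, clean_filtered):
        assert make_training_windows(clean_filtered, AnnotationTrack([])) == []


def _toy_windows(n, length, target, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        w = rng.standard_normal(length)
        w = (w - w.mean()) / w.std()
        out.append(TrainingWindow(samples=w, target_offset=target))
    return out


class TestTraining:
    def test_zero_target_degenerate_fit(self, clean_filtered, clean_truth):
        # all targets forced to zero: the model must learn the constant map
        # and generalize it to unseen windows of the same signal family
        train = make_training_windows(clean_filtered, clean_truth, channels=[0, 1, 2])
        held = make_training_windows(clean_filtered, clean_truth, channels=[3])
        for w in train:
            w.target_offset = 0.0
        model = train_peak_model(
            train,
            StoppingCriteria(error_tol=1e-5, margin_tol=1e-5, max_epochs=40),
            seed=0,
        )
        preds = model.predict_offsets(np.stack([w.samples for w in held]))
        assert np.all(np.abs(preds) < 0.02)

    def test_same_seed_identical_loss_curve(self):
        train = _toy_windows(60, 150, 0.1, seed=3)
        a = train_peak_model(train, StoppingCriteria(max_epochs=5), seed=4, fs=100.0, window_s=1.5)
        b = train_peak_model(train, StoppingCriteria(max_epochs=5), seed=4, fs=100.0, window_s=1.5)
        assert a.loss_history == b.loss_history

    def test_inconsistent_lengths_rejected(self):
        wins = _toy_windows(3, 150, 0.0) + _toy_windows(1, 151, 0.0)
        with pytest.raises(InputError, match="inconsistent"):
            train_peak_model(wins, fs=100.0, window_s=1.5)

    def test_empty_windows_rejected(self):
        with pytest.raises(InputError):
            train_peak_model([])

    def test_stopping_criteria_recorded(self):
        train = _toy_windows(60, 150, 0.0, seed=5)
        model = train_peak_model(
            train, StoppingCriteria(max_epochs=50), seed=0, fs=100.0, window_s=1.5
        )
        assert model.meta["epochs"] == len(model.loss_history) <= 50
        assert model.trained

    def test_held_out_accuracy_on_clean_subject(self, trained_model, clean_filtered, clean_truth):
        wins = make_training_windows(clean_filtered, clean_truth, channels=[1])
        x = np.stack([w.samples for w in wins])
        y = np.array([w.target_offset for w in wins])
        preds = trained_model.predict_offsets(x)
        assert np.mean(np.abs(preds - y)) < 0.05


class TestPredict:
    def test_untrained_model_raises(self):
        model = PeakModel(fs=100.0, window_s=1.5)
        with pytest.raises(StateError):
            predict_r_peaks(model, np.zeros(1000), fs=100.0)

    def test_zero_candidates_empty_track(self, trained_model):
        track = predict_r_peaks(trained_model, np.zeros(4000), fs=FS)
        assert len(track) == 0
        assert track.source == "bcg-predicted"

    def test_predictions_ascending_with_min_spacing(self, trained_model, clean_filtered):
        track = predict_r_peaks(trained_model, clean_filtered.data[0], fs=FS)
        assert np.all(np.diff(track.event_times) >= 0.3 - 1e-12)

    def test_count_matches_truth_on_clean_data(self, trained_model, clean_filtered, clean_pair):
        track = predict_r_peaks(trained_model, clean_filtered.data[0], fs=FS)
        # beats whose J lies within half a window (1.5 s) of either end have
        # no full 3-s context and are legitimately absent
        j = clean_pair.true_j_times
        interior = ((j >= 1.5) & (j <= clean_pair.bcg.duration - 1.5)).sum()
        assert interior <= len(track) <= clean_pair.true_r_times.size

    def test_offset_correction_reduces_jitter(self, trained_model, clean_filtered, clean_pair):
        raw = predict_r_peaks(
            trained_model, clean_filtered.data[0], fs=FS, offset_correction=0.0
        )
        corrected = predict_r_peaks(trained_model, clean_filtered.data[0], fs=FS)
        truth = clean_pair.true_r_times

        def jitter(track):
            e = np.asarray(
                [truth[np.abs(truth - t).argmin()] - t for t in track.event_times]
            )
            return e[np.abs(e) < 0.1].std()

        assert jitter(corrected) <= jitter(raw) + 1e-12

    def test_prediction_error_small_on_clean_data(self, trained_model, clean_filtered, clean_pair):
        track = predict_r_peaks(trained_model, clean_filtered.data[0], fs=FS)
        truth = clean_pair.true_r_times
        errs = [np.abs(truth - t).min() for t in track.event_times]
        assert np.median(errs) < 0.05


class TestModelSerialization:
    def test_round_trip(self, tmp_path, trained_model, clean_filtered):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        back = PeakModel.load(path)
        x = clean_filtered.data[0][:600]
        x = (x - x.mean()) / x.std()
        np.testing.assert_array_equal(
            trained_model.predict_offsets(x), back.predict_offsets(x)
        )
        assert back.trained and back.fs == trained_model.fs


class TestBaseline:
    def test_detects_every_j_on_clean_train(self):
        template = beat_force_waveform(AorticParams(), FS)
        rec, j_times = synth_bcg(
            np.full(8, 1.0), template, ChannelLayout(), BridgeParams(),
            fs=FS, duration=10.0,
        )
        filt = bandpass(rec)
        track = baseline_peak_detect(filt.data[0], FS)
        assert len(track) >= j_times.size
        for jt in j_times:
            assert np.abs(track.event_times - jt).min() < 0.05

    def test_all_zero_signal_empty(self):
        assert len(baseline_peak_detect(np.zeros(2000), FS)) == 0

    def test_noise_bursts_inflate_count(self):
        template = beat_force_waveform(AorticParams(), FS)
        layout = ChannelLayout(noise_sd=2.0, motion_artifact_rate=30.0)
        rec, j_times = synth_bcg(
            np.full(28, 1.0), template, layout, BridgeParams(),
            fs=FS, duration=30.0, seed=13,
        )
        filt = bandpass(rec)
        track = baseline_peak_detect(filt.data[0], FS)
        assert len(track) >= j_times.size

    def test_time_offset_shifts_track(self):
        x = np.zeros(2000)
        x[1000] = 1.0
        a = baseline_peak_detect(x, FS)
        b = baseline_peak_detect(x, FS, time_offset=0.25)
        np.testing.assert_allclose(b.event_times, a.event_times - 0.25)
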