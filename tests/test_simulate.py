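import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcgkit.errors import InputError, ParameterError
from bcgkit.preprocess import bandpass
from bcgkit.simulate import (
    AorticParams,
    BridgeParams,
    CardiacParams,
    ChannelLayout,
    beat_force_waveform,
    bridge_output,
    generate_rr_intervals,
    simulate_cohort,
    simulate_paired,
    synth_bcg,
    synth_ecg,
)


class TestGenerateRRIntervals:
    def test_constant_rr(self):
        rr = generate_rr_intervals(
            CardiacParams(mean_rr=0.8, rr_sd=0.0, rsa_amplitude=0.0, duration=4.0)
        )
        np.testing.assert_allclose(rr, [0.8] * 5)

    def test_sample_mean_clt_bound(self):
        # Monte-Carlo oracle: sample mean of ~300 Gaussian draws stays within
        # 3 standard errors of the configured mean
        rr = generate_rr_intervals(
            CardiacParams(
                mean_rr=0.85, rr_sd=0.05, rsa_amplitude=0.0, duration=300 * 0.85,
                seed=17,
            )
        )
        n = rr.size
        assert n > 250
        assert abs(rr.mean() - 0.85) < 3 * 0.05 / np.sqrt(n)

    def test_seed_reproducibility(self):
        p = CardiacParams(duration=30.0, seed=3)
        np.testing.assert_array_equal(
            generate_rr_intervals(p), generate_rr_intervals(p)
        )

    def test_cumsum_within_duration_and_clipping(self):
        rr = generate_rr_intervals(
            CardiacParams(mean_rr=0.5, rr_sd=0.3, duration=50.0, seed=1)
        )
        assert rr.sum() <= 50.0
        assert np.all(rr >= 0.4) and np.all(rr <= 1.5)

    def test_invalid_duration(self):
        with pytest.raises(ParameterError):
            generate_rr_intervals(CardiacParams(duration=-1.0))


class TestBridge:
    def test_balanced_bridge_is_zero(self):
        assert bridge_output(BridgeParams(350, 350, 350, 350, 5.0)) == 0.0

    def test_unbalanced_hand_computed(self):
        # 351*350 - 350*350 = 350; (351+350)*(350+350) = 701*700
        expected = 350.0 / (701.0 * 700.0) * 5.0
        got = bridge_output(BridgeParams(351, 350, 350, 350, 5.0))
        assert got == pytest.approx(expected, abs=1e-15)
        assert got == pytest.approx(3.566e-3, rel=1e-3)

    def test_zero_excitation(self):
        assert bridge_output(BridgeParams(1, 2, 3, 4, 0.0)) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        r=st.floats(1.0, 1e4),
        e=st.floats(-100.0, 100.0),
    )
    def test_balanced_bridge_property(self, r, e):
        assert bridge_output(BridgeParams(r, r, r, r, e)) == 0.0

    def test_nonpositive_resistance(self):
        with pytest.raises(ParameterError):
            bridge_output(BridgeParams(0, 350, 350, 350, 5.0))


class TestBeatForceWaveform:
    def test_equal_pressures_zero(self):
        aortic = AorticParams(
            propagation_delay_01=0.0, propagation_delay_12=0.0,
            attenuation_01=1.0, attenuation_12=1.0,
        )
        np.testing.assert_allclose(beat_force_waveform(aortic, 200.0), 0.0)

    def test_pointwise_formula(self):
        # direct evaluation: A_D=1, A_A=1, P1-P2=2, P0-P1=1 -> force = 1
        assert 1.0 * 2.0 - 1.0 * 1.0 == 1.0  # the formula itself
        aortic = AorticParams()
        p0 = np.array([3.0])
        p1 = np.array([2.0])
        p2 = np.array([0.0])
        force = aortic.area_descending * (p1 - p2) - aortic.area_ascending * (p0 - p1)
        expected = 3.0 * 2.0 - 5.0 * 1.0
        assert force[0] == expected

    def test_ijk_ordering(self):
        t = beat_force_waveform(AorticParams(), 200.0)
        j = int(np.argmax(t))
        i = int(np.argmin(t[:j]))
        k = j + int(np.argmin(t[j:]))
        assert i < j < k
        assert t[i] < 0 and t[k] < 0
        assert t[j] == t.max() > 0

    def test_bad_fs(self):
        with pytest.raises(ParameterError):
            beat_force_waveform(AorticParams(), -1.0)


class TestSynthEcg:
    def test_single_beat_argmax(self):
        rec, samples = synth_ecg(np.array([1.0]), fs=200.0, duration=2.0)
        assert int(np.argmax(rec.data[0])) == 200
        np.testing.assert_array_equal(samples, [200])

    def test_three_beats_three_maxima(self):
        rec, _ = synth_ecg(np.array([0.8, 1.6, 2.4]), fs=200.0, duration=3.2)
        x = rec.data[0]
        half_height = x.max() / 2
        count = sum(
            1
            for i in range(1, x.size - 1)
            if x[i] > half_height and x[i] >= x[i - 1] and x[i] > x[i + 1]
        )
        assert count == 3

    def test_empty_r_times(self):
        rec, samples = synth_ecg(np.array([]), fs=200.0, duration=1.0)
        np.testing.assert_array_equal(rec.data, 0.0)
        assert samples.size == 0

    def test_unsorted_rejected(self):
        with pytest.raises(InputError):
            synth_ecg(np.array([1.0, 0.5]), fs=200.0, duration=2.0)


class TestSynthBcg:
    def _template(self):
        return beat_force_waveform(AorticParams(), 200.0)

    def test_single_weight_channel(self):
        layout = ChannelLayout(weights=(1.0, 0.0, 0.0, 0.0))
        rec, _ = synth_bcg(
            np.array([0.8, 0.8]), self._template(), layout, BridgeParams(),
            fs=200.0, duration=3.0,
        )
        assert np.ptp(rec.data[0]) > 0
        np.testing.assert_array_equal(rec.data[1:], 0.0)

    def test_j_peak_count_and_spacing(self):
        rr = np.full(9, 1.0)
        rec, j_times = synth_bcg(
            rr, self._template(), ChannelLayout(), BridgeParams(),
            fs=200.0, duration=10.0,
        )
        assert j_times.size == 10  # beat at t=0 plus 9 cumulative intervals
        np.testing.assert_allclose(np.diff(j_times), 1.0)

    def test_seed_reproducibility(self):
        layout = ChannelLayout(noise_sd=3.0, motion_artifact_rate=5.0)
        args = (np.full(4, 0.8), self._template(), layout, BridgeParams())
        a, _ = synth_bcg(*args, fs=200.0, duration=5.0, seed=9)
        b, _ = synth_bcg(*args, fs=200.0, duration=5.0, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ParameterError, match="sum to 1"):
            synth_bcg(
                np.array([0.8]), self._template(),
                ChannelLayout(weights=(0.5, 0.5, 0.5, 0.5)), BridgeParams(),
                fs=200.0, duration=2.0,
            )


class TestPairedAndCohort:
    def test_paired_invariants(self, clean_pair):
        p = clean_pair
        assert p.true_r_times.size == p.true_j_times.size
        assert np.all(p.true_j_times > p.true_r_times)
        assert p.true_r_times[0] >= 0
        assert p.true_j_times[-1] <= p.bcg.duration
        assert p.bcg.n_channels == 4 and p.ecg.n_channels == 1

    def test_latency_exact_in_noiseless_mode(self, clean_pair):
        np.testing.assert_array_equal(
            clean_pair.true_j_times - clean_pair.true_r_times, 0.25
        )

    def test_latency_jitter_bounds(self):
        pair = simulate_paired(
            CardiacParams(duration=30.0, seed=2), latency_jitter_sd=0.01
        )
        lat = pair.true_j_times - pair.true_r_times
        assert np.all(np.abs(lat - 0.25) < 0.06)  # 6 sigma

    def test_clean_amplitude_inside_qc_band(self, clean_pair):
        x = clean_pair.bcg.data[0]
        p2p = [np.ptp(x[i : i + 200]) for i in range(200, x.size - 200, 100)]
        assert 35 < min(p2p) and max(p2p) < 85

    def test_cohort_basic(self):
        cohort = simulate_cohort(2, duration=30.0, seed=5)
        assert len(cohort) == 2
        for p in cohort:
            assert p.bcg.duration == pytest.approx(30.0)

    def test_cohort_ten_minute_subjects(self):
        # scaled instance of the recording protocol: long recordings work
        cohort = simulate_cohort(1, duration=600.0, seed=6)
        assert cohort[0].bcg.duration == pytest.approx(600.0)
        assert cohort[0].true_r_times.size > 500

    def test_cohort_determinism(self):
        a = simulate_cohort(3, duration=20.0, seed=8, clean=False)
        b = simulate_cohort(3, duration=20.0, seed=8, clean=False)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.bcg.data, pb.bcg.data)
            np.testing.assert_array_equal(pa.true_r_times, pb.true_r_times)

    def test_cohort_validation(self):
        with pytest.raises(ParameterError):
            simulate_cohort(0)
        with pytest.raises(ParameterError):
            simulate_cohort(1, mean_rr_range=(1.0, 0.7))

    def test_j_peaks_present_in_filtered_signal(self, clean_pair):
        # every true J time coincides with a local maximum of the filtered BCG
        filt = bandpass(clean_pair.bcg)
        x = filt.data[0]
        for jt in clean_pair.true_j_times[1:-1]:
            s = int(round(jt * 200.0))
            lo, hi = max(0, s - 10), s + 11
            assert np.argmax(x[lo:hi]) + lo == pytest.approx(s, abs=2)
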