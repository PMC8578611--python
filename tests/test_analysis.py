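"""Analysis chain: filters, HFO detection, SNR, spikes, ISI, latency map."""

import numpy as np
import pytest
import scipy.signal
from hypothesis import given
from hypothesis import strategies as st

from mea3d import (
    ArrayLayout,
    ArrayRecording,
    BandDefinition,
    DetectionParams,
    EventSchedule,
    HfoEvent,
    IctalBurst,
    RecordingConfig,
    SpikeEvent,
    apply_zero_phase,
    bandpass_filter,
    compute_snr,
    detect_hfo,
    detect_spikes,
    fir_bandpass,
    generate_noise,
    generate_recording,
    isi,
    onset_latency_map,
)
from mea3d.analysis import FAST_RIPPLE, RIPPLE, match_event_times, snr_p2p

RATE = 2000.0


def gain_at(coeffs: np.ndarray, freq: float, rate: float) -> float:
    _, h = scipy.signal.freqz(coeffs, worN=[freq], fs=rate)
    return float(np.abs(h[0]))


class TestFirFilter:
    def test_passband_gain_near_unity(self):
        coeffs = fir_bandpass(RIPPLE, RATE, 513)
        assert 0.95 <= gain_at(coeffs, 100.0, RATE) <= 1.05

    def test_minus_six_db_points_at_band_edges(self):
        coeffs = fir_bandpass(RIPPLE, RATE, 513)
        for edge in (RIPPLE.low_hz, RIPPLE.high_hz):
            assert gain_at(coeffs, edge, RATE) == pytest.approx(0.5, abs=0.05)

    def test_stopband_attenuation_one_octave_out(self):
        coeffs = fir_bandpass(RIPPLE, RATE, 513)
        # one octave above the upper edge
        assert 20 * np.log10(gain_at(coeffs, 500.0, RATE)) < -40.0
        assert 20 * np.log10(gain_at(coeffs, 400.0, RATE)) < -40.0

    def test_coefficients_symmetric(self):
        coeffs = fir_bandpass(FAST_RIPPLE, RATE, 257)
        np.testing.assert_allclose(coeffs, coeffs[::-1], rtol=0, atol=1e-15)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fir_bandpass(FAST_RIPPLE, 1000.0, 513)

    def test_even_taps_rejected(self):
        with pytest.raises(ValueError):
            fir_bandpass(RIPPLE, RATE, 512)


class TestZeroPhase:
    def test_impulse_stays_at_its_sample(self):
        coeffs = fir_bandpass(RIPPLE, RATE, 101)
        x = np.zeros(2000)
        x[700] = 1.0
        y = apply_zero_phase(coeffs, x)
        assert int(np.argmax(np.abs(y))) == 700

    def test_zeros_stay_zeros(self):
        coeffs = fir_bandpass(RIPPLE, RATE, 101)
        assert not apply_zero_phase(coeffs, np.zeros(1000)).any()

    def test_inband_sine_gain_is_squared_response(self):
        coeffs = fir_bandpass(RIPPLE, RATE, 513)
        t = np.arange(8000) / RATE
        x = np.sin(2 * np.pi * 150.0 * t)
        y = apply_zero_phase(coeffs, x)
        mid = slice(2000, 6000)
        expected = gain_at(coeffs, 150.0, RATE) ** 2
        assert np.max(np.abs(y[mid])) == pytest.approx(expected, rel=0.01)
        # zero phase: in-band sine stays aligned with the input
        assert np.dot(x[mid], y[mid]) / (
            np.linalg.norm(x[mid]) * np.linalg.norm(y[mid])
        ) == pytest.approx(1.0, abs=1e-4)

    def test_short_series_rejected(self):
        coeffs = fir_bandpass(RIPPLE, RATE, 513)
        with pytest.raises(ValueError):
            apply_zero_phase(coeffs, np.zeros(1000))


def _atom_recording(freq: float, n_atoms: int, seed: int, amplitude: float = 100e-6):
    layout = ArrayLayout.strip(2, 500.0)
    cfg = RecordingConfig(duration_s=12.0, seed=seed)
    times = np.linspace(2.0, 11.0, n_atoms)
    duration = 0.05 if freq < 250 else 0.02
    events = tuple(
        HfoEvent(i % 2, t, freq, duration, amplitude) for i, t in enumerate(times)
    )
    rec = generate_recording(layout, cfg, EventSchedule(hfo_events=events))
    return rec


class TestDetectHfo:
    def test_recall_and_precision_on_injected_ripples(self):
        rec = _atom_recording(120.0, 10, seed=21)
        detected = detect_hfo(rec, RIPPLE)
        truth = rec.ground_truth
        matched = fp = missed = 0
        for ch in (0, 1):
            m, f, s = match_event_times(
                detected.query("channel_id == @ch").time_s.to_numpy(),
                truth.query("channel_id == @ch").time_s.to_numpy(),
                tolerance_s=0.010,
            )
            matched, fp, missed = matched + m, fp + f, missed + s
        recall = matched / (matched + missed)
        precision = matched / (matched + fp)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_fast_ripple_atoms_classified_in_fast_band_only(self):
        rec = _atom_recording(400.0, 6, seed=22)
        in_fast = detect_hfo(rec, FAST_RIPPLE)
        in_ripple = detect_hfo(rec, RIPPLE)
        assert len(in_fast) >= 5
        assert len(in_ripple) == 0

    def test_ripple_atoms_not_seen_in_fast_band(self):
        rec = _atom_recording(120.0, 6, seed=23)
        assert len(detect_hfo(rec, FAST_RIPPLE)) == 0

    def test_false_positive_rate_under_null(self):
        layout = ArrayLayout.strip(2, 500.0)
        cfg = RecordingConfig(duration_s=60.0, seed=31)
        rec = generate_recording(layout, cfg, EventSchedule())
        events = detect_hfo(rec, RIPPLE)
        # at the 5 SD default: at most ~1 false event per minute per channel
        assert len(events) <= 2

    def test_empty_baseline_rejected(self):
        rec = _atom_recording(120.0, 2, seed=24)
        params = DetectionParams(baseline_window_s=(0.0, 0.0001))
        with pytest.raises(ValueError):
            detect_hfo(rec, RIPPLE, params)


class TestSnr:
    def _constructed_recording(self, seizure_p2p: float, noise_p2p: float):
        """Deterministic sines: every 100 ms window has an exact p2p."""
        rate = RATE
        t = np.arange(int(10 * rate)) / rate
        x = (noise_p2p / 2.0) * np.sin(2 * np.pi * 100.0 * t)
        seiz = slice(int(4 * rate), int(6 * rate))
        x[seiz] = (seizure_p2p / 2.0) * np.sin(2 * np.pi * 100.0 * t[seiz])
        layout = ArrayLayout.strip(1, 500.0)
        cfg = RecordingConfig(duration_s=10.0, noise_p2p=0.0, seed=0)
        return ArrayRecording(
            layout=layout,
            config=cfg,
            samples=x[np.newaxis, :],
            ground_truth=generate_recording(layout, cfg, EventSchedule()).ground_truth,
        )

    def test_printed_amplitudes_give_160(self):
        # 3.2 mV seizure over 20 µV baseline
        rec = self._constructed_recording(3.2e-3, 20e-6)
        snr = compute_snr(rec, 0, (4.0, 6.0), [(0.0, 4.0), (6.0, 10.0)])
        assert snr == pytest.approx(160.0, rel=1e-3)

    def test_identical_statistics_give_unity(self):
        rec = self._constructed_recording(20e-6, 20e-6)
        snr = compute_snr(rec, 0, (4.0, 6.0), [(0.0, 4.0), (6.0, 10.0)])
        assert snr == pytest.approx(1.0, rel=1e-3)

    @given(gain=st.floats(0.1, 1000.0))
    def test_invariant_to_global_gain(self, gain):
        rec = self._constructed_recording(1e-3, 20e-6)
        scaled = ArrayRecording(
            layout=rec.layout,
            config=rec.config,
            samples=rec.samples * gain,
            ground_truth=rec.ground_truth,
        )
        s1 = compute_snr(rec, 0, (4.0, 6.0), [(0.0, 4.0)])
        s2 = compute_snr(scaled, 0, (4.0, 6.0), [(0.0, 4.0)])
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_overlapping_windows_rejected(self):
        rec = self._constructed_recording(1e-3, 20e-6)
        with pytest.raises(ValueError):
            compute_snr(rec, 0, (4.0, 6.0), [(5.0, 7.0)])

    def test_zero_noise_is_diagnostic_failure(self):
        x = np.zeros(int(10 * RATE))
        with pytest.raises(ZeroDivisionError):
            snr_p2p(x + 1.0, RATE, (4.0, 6.0), [(0.0, 4.0)])


class TestSpikes:
    def test_injected_spikes_recovered_exactly(self):
        layout = ArrayLayout.strip(1, 500.0)
        cfg = RecordingConfig(duration_s=5.0, seed=41)
        sd = float(np.std(generate_noise(cfg, 1)[0]))
        sched = EventSchedule(
            spike_events=tuple(
                SpikeEvent(0, t, 8.0 * sd) for t in (1.0, 2.0, 3.0)
            )
        )
        rec = generate_recording(layout, cfg, sched)
        ts = detect_spikes(rec.samples[0], RATE, k_sd=5.0, refractory_s=1e-3)
        assert len(ts) == 3
        np.testing.assert_allclose(ts, [1.0, 2.0, 3.0], atol=1e-3)

    def test_noise_only_false_positives_below_gaussian_bound(self):
        cfg = RecordingConfig(duration_s=60.0, seed=42)
        noise = generate_noise(cfg, 1)[0]
        ts = detect_spikes(noise, RATE, k_sd=5.0, refractory_s=1e-3)
        assert len(ts) <= 1

    def test_refractory_merges_close_spikes(self):
        x = np.zeros(4000)
        x[1000] = x[1001] = -1.0  # two crossings 0.5 ms apart at 2 kHz
        x[:500] = 0.01 * np.sin(np.arange(500))  # nonzero baseline SD
        ts = detect_spikes(x, RATE, k_sd=5.0, refractory_s=1e-3)
        assert len(ts) == 1

    def test_sub_sample_refractory_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(100), RATE, k_sd=5.0, refractory_s=1e-5)


class TestIsi:
    def test_first_differences(self):
        np.testing.assert_allclose(isi([0.1, 0.3, 0.35]), [0.2, 0.05])

    def test_single_timestamp_empty(self):
        assert len(isi([0.5])) == 0

    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=30))
    def test_intervals_telescope(self, ts):
        ts = sorted(ts)
        assert np.sum(isi(ts)) == pytest.approx(ts[-1] - ts[0], abs=1e-9)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            isi([0.3, 0.1])


ONSET_BAND = BandDefinition("onset", 40.0, 120.0)


class TestLatencyMap:
    def test_corner_focus_lags_recovered(self):
        layout = ArrayLayout.grid(8, 8, 500.0)
        cfg = RecordingConfig(duration_s=4.0, seed=3)
        sched = EventSchedule(
            ictal_bursts=(IctalBurst(start_s=1.5, end_s=2.5, amplitude_p2p=1e-3),),
            focus_um=(0.0, 0.0),
            propagation_speed_um_s=1e4,
        )
        rec = generate_recording(layout, cfg, sched)
        lat, order = onset_latency_map(rec, ONSET_BAND)
        pos = np.asarray(layout.positions_um)
        true_lag = np.hypot(pos[:, 0], pos[:, 1]) / 1e4
        true_lag -= true_lag.min()
        for i, ch in enumerate(layout.channel_ids):
            assert lat[ch] == pytest.approx(true_lag[i], abs=0.010)
        assert order[0] == 0  # the focus channel leads

    def test_two_channel_strip_lag(self):
        layout = ArrayLayout.strip(2, 350.0)
        cfg = RecordingConfig(duration_s=4.0, seed=5)
        sched = EventSchedule(
            ictal_bursts=(IctalBurst(start_s=1.5, end_s=2.5, amplitude_p2p=1e-3),),
            focus_um=(0.0, 0.0),
            propagation_speed_um_s=1e4,
        )
        rec = generate_recording(layout, cfg, sched)
        lat, _ = onset_latency_map(rec, ONSET_BAND)
        assert lat[1] == pytest.approx(350.0 / 1e4, abs=0.010)

    def test_identical_channels_tie_broken_by_id(self):
        # both channels equidistant from the focus, no noise: zero lags
        layout = ArrayLayout.strip(2, 350.0)
        cfg = RecordingConfig(duration_s=4.0, noise_p2p=0.0, seed=0)
        sched = EventSchedule(
            ictal_bursts=(IctalBurst(start_s=1.5, end_s=2.5, amplitude_p2p=1e-3),),
            focus_um=(175.0, 0.0),
        )
        rec = generate_recording(layout, cfg, sched)
        lat, order = onset_latency_map(rec, ONSET_BAND)
        assert lat[0] == lat[1] == 0.0
        assert order == [0, 1]

    def test_ordering_invariant_to_channel_gain(self):
        layout = ArrayLayout.grid(2, 2, 500.0)
        cfg = RecordingConfig(duration_s=4.0, seed=6)
        sched = EventSchedule(
            ictal_bursts=(IctalBurst(start_s=1.5, end_s=2.5, amplitude_p2p=1e-3),),
            focus_um=(0.0, 0.0),
            propagation_speed_um_s=5e3,
        )
        rec = generate_recording(layout, cfg, sched)
        gains = np.array([1.0, 0.3, 3.0, 0.5])[:, np.newaxis]
        scaled = ArrayRecording(
            layout=layout, config=cfg, samples=rec.samples * gains,
            ground_truth=rec.ground_truth,
        )
        _, order1 = onset_latency_map(rec, ONSET_BAND)
        _, order2 = onset_latency_map(scaled, ONSET_BAND)
        assert order1 == order2

    def test_no_crossings_is_diagnostic_failure(self):
        layout = ArrayLayout.strip(2, 350.0)
        cfg = RecordingConfig(duration_s=4.0, seed=8)
        rec = generate_recording(layout, cfg, EventSchedule())
        with pytest.raises(RuntimeError):
            onset_latency_map(rec, ONSET_BAND)
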