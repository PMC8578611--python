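"""Recording analysis: band decomposition, HFO detection, SNR, spikes, ISI,
and onset-latency propagation mapping.

The chain mirrors how seizure recordings from the arrays are processed:
raw LFP is bandpass filtered with linear-phase FIR filters into the ripple
(80-250 Hz) and fast-ripple (250-500 Hz) bands, applied forward-backward
so event times are not delayed; high-frequency oscillations are detected
where the RMS envelope of the filtered trace exceeds a baseline-derived
threshold for at least a few carrier cycles; the SNR statistic is the
maximum peak-to-peak amplitude during seizure onset divided by the mean
windowed peak-to-peak amplitude of the inter-ictal baseline; spikes are
negative threshold crossings with a refractory period; and seizure
propagation is mapped from the per-channel latency of the first
suprathreshold envelope crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
from scipy.ndimage import uniform_filter1d

from .synth import ArrayRecording, windowed_p2p_mean

__all__ = [
    "BandDefinition",
    "DetectionParams",
    "RIPPLE",
    "FAST_RIPPLE",
    "fir_bandpass",
    "apply_zero_phase",
    "bandpass_filter",
    "detect_hfo",
    "compute_snr",
    "detect_spikes",
    "isi",
    "onset_latency_map",
    "match_event_times",
]

EVENT_COLUMNS = ["channel_id", "type", "time_s", "duration_s", "peak_v", "band"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("band must satisfy 0 < low < high")

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


RIPPLE = BandDefinition("ripple", 80.0, 250.0)
FAST_RIPPLE = BandDefinition("fast_ripple", 250.0, 500.0)


@dataclass(frozen=True)
class DetectionParams:
    """HFO/onset detection settings.

    The envelope is the sliding RMS of the band-filtered trace over
    ``envelope_window_s``; events are where it exceeds the baseline mean
    plus ``threshold_k`` baseline standard deviations for at least
    ``min_cycles`` carrier cycles, with gaps shorter than the envelope
    window merged.  ``baseline_window_s`` is an event-free stretch used to
    estimate the baseline statistics.
    """

    envelope_window_s: float = 0.010
    threshold_k: float = 5.0
    min_cycles: int = 4
    baseline_window_s: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.envelope_window_s <= 0 or self.threshold_k <= 0 or self.min_cycles <= 0:
            raise ValueError("detection parameters must be positive")
        if self.baseline_window_s[1] <= self.baseline_window_s[0]:
            raise ValueError("baseline window must have positive length")


def default_n_taps(rate: float) -> int:
    """Filter length scaled with the sampling rate: 513 taps at 2 kHz."""
    n = int(round(513 * rate / 2000.0))
    return n if n % 2 == 1 else n + 1


def fir_bandpass(band: BandDefinition, rate: float, n_taps: int | None = None) -> np.ndarray:
    """Linear-phase Hamming-windowed-sinc bandpass coefficients.

    Half-amplitude (-6 dB) points sit at the band edges; attenuation one
    octave outside the band exceeds 40 dB at the default length.
    """
    if band.high_hz >= rate / 2.0:
        raise ValueError("band edge at or above Nyquist")
    if n_taps is None:
        n_taps = default_n_taps(rate)
    if n_taps % 2 != 1:
        raise ValueError("n_taps must be odd")
    return scipy.signal.firwin(
        n_taps, [band.low_hz, band.high_hz], pass_zero=False, window="hamming", fs=rate
    )


def apply_zero_phase(coeffs: np.ndarray, series: np.ndarray) -> np.ndarray:
    """Forward-backward FIR application (zero net group delay)."""
    if len(series) <= 3 * len(coeffs):
        raise ValueError("series must be longer than 3x the filter length")
    return scipy.signal.filtfilt(coeffs, [1.0], series)


def bandpass_filter(
    series: np.ndarray, band: BandDefinition, rate: float, n_taps: int | None = None
) -> np.ndarray:
    """Zero-phase bandpass of one trace."""
    return apply_zero_phase(fir_bandpass(band, rate, n_taps), series)


def _rms_envelope(series: np.ndarray, rate: float, window_s: float) -> np.ndarray:
    w = max(1, int(round(window_s * rate)))
    # clamp tiny negative round-off from the uniform filter
    return np.sqrt(np.maximum(uniform_filter1d(series**2, size=w, mode="nearest"), 0.0))


def _slice(rate: float, window: tuple[float, float]) -> slice:
    return slice(int(round(window[0] * rate)), int(round(window[1] * rate)))


def _merge_runs(above: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Contiguous True runs of ``above``, merging gaps <= max_gap samples."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    return list(zip(starts, ends + 1))


def detect_hfo(
    recording: ArrayRecording,
    band: BandDefinition,
    params: DetectionParams | None = None,
    n_taps: int | None = None,
) -> pd.DataFrame:
    """Detect HFO events per channel in one band.

    Returns an event table (:data:`EVENT_COLUMNS`) with ``time_s`` at the
    envelope peak, the suprathreshold duration, and the peak absolute
    amplitude of the band-filtered trace within the event.
    """
    params = params or DetectionParams()
    rate = recording.config.sampling_rate_hz
    base = _slice(rate, params.baseline_window_s)
    if base.stop <= base.start:
        raise ValueError("empty baseline window")
    min_dur = params.min_cycles / band.center_hz
    max_gap = int(round(params.envelope_window_s * rate))
    rows = []
    for ch_idx, ch_id in enumerate(recording.layout.channel_ids):
        filt = bandpass_filter(recording.samples[ch_idx], band, rate, n_taps)
        env = _rms_envelope(filt, rate, params.envelope_window_s)
        mu, sd = env[base].mean(), env[base].std()
        thr = mu + params.threshold_k * sd
        for start, stop in _merge_runs(env > thr, max_gap):
            duration = (stop - start) / rate
            if duration < min_dur:
                continue
            peak_idx = start + int(np.argmax(env[start:stop]))
            rows.append(
                (
                    ch_id,
                    f"hfo_{band.name}",
                    peak_idx / rate,
                    duration,
                    float(np.max(np.abs(filt[start:stop]))),
                    band.name,
                )
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def snr_p2p(
    series: np.ndarray,
    rate: float,
    seizure_window: tuple[float, float],
    interictal_windows: list[tuple[float, float]],
    noise_window_s: float = 0.1,
) -> float:
    """Peak-to-peak SNR of one trace.

    Numerator: maximum peak-to-peak amplitude (max minus min) inside the
    seizure-onset window.  Denominator: mean peak-to-peak amplitude over
    non-overlapping ``noise_window_s`` windows within the inter-ictal
    stretches.
    """
    sz = series[_slice(rate, seizure_window)]
    if sz.size == 0:
        raise ValueError("empty seizure window")
    numerator = float(sz.max() - sz.min())
    p2ps = []
    for window in interictal_windows:
        seg = series[_slice(rate, window)]
        if seg.size == 0:
            raise ValueError("empty inter-ictal window")
        p2ps.append(windowed_p2p_mean(seg, rate, noise_window_s))
    denominator = float(np.mean(p2ps))
    if denominator == 0:
        raise ZeroDivisionError("inter-ictal noise amplitude is zero")
    return numerator / denominator


def compute_snr(
    recording: ArrayRecording,
    channel_id: int,
    seizure_window: tuple[float, float],
    interictal_windows: list[tuple[float, float]],
    noise_window_s: float = 0.1,
) -> float:
    """Peak-to-peak SNR for one channel of a recording; see :func:`snr_p2p`."""
    for window in interictal_windows:
        if window[0] < seizure_window[1] and seizure_window[0] < window[1]:
            raise ValueError("inter-ictal windows must not overlap the seizure window")
    return snr_p2p(
        recording.channel(channel_id),
        recording.config.sampling_rate_hz,
        seizure_window,
        interictal_windows,
        noise_window_s,
    )


def detect_spikes(
    series: np.ndarray,
    rate: float,
    k_sd: float = 5.0,
    refractory_s: float = 1e-3,
    baseline_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Negative-going threshold-crossing spike timestamps (s).

    The threshold is ``-k_sd`` times the standard deviation of the
    baseline stretch (whole trace if none is given); a crossing is the
    first sample below threshold, and further crossings within the
    refractory period are suppressed.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    refractory = int(round(refractory_s * rate))
    if refractory < 1:
        raise ValueError("refractory period must be at least one sample")
    base = series if baseline_window is None else series[_slice(rate, baseline_window)]
    thr = -k_sd * float(np.std(base))
    below = series < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below[0]:
        crossings = np.r_[0, crossings]
    kept = []
    last = -np.inf
    for c in crossings:
        if c - last >= refractory:
            kept.append(c)
            last = c
    return np.asarray(kept) / rate


def isi(timestamps: np.ndarray) -> np.ndarray:
    """Inter-spike intervals: first differences of sorted timestamps."""
    ts = np.asarray(timestamps, dtype=float)
    if np.any(np.diff(ts) < 0):
        raise ValueError("timestamps must be sorted")
    return np.diff(ts)


def onset_latency_map(
    recording: ArrayRecording,
    band: BandDefinition,
    params: DetectionParams | None = None,
    n_taps: int | None = None,
) -> tuple[dict[int, float], list[int]]:
    """Per-channel onset latency of the first suprathreshold envelope
    crossing, relative to the earliest channel.

    The onset is the start of the first crossing sustained for at least
    ``min_cycles`` carrier cycles (gaps shorter than the envelope window
    merged), which rejects isolated noise blips.  Returns
    ``(latencies, ordering)`` where ``ordering`` sorts channels by latency
    with ties broken by channel id.  Channels that never cross are
    omitted; fewer than two crossing channels is an error since no
    propagation can be mapped.
    """
    params = params or DetectionParams()
    rate = recording.config.sampling_rate_hz
    base = _slice(rate, params.baseline_window_s)
    min_dur = params.min_cycles / band.center_hz
    max_gap = int(round(params.envelope_window_s * rate))
    onsets: dict[int, float] = {}
    for ch_idx, ch_id in enumerate(recording.layout.channel_ids):
        filt = bandpass_filter(recording.samples[ch_idx], band, rate, n_taps)
        env = _rms_envelope(filt, rate, params.envelope_window_s)
        thr = env[base].mean() + params.threshold_k * env[base].std()
        for start, stop in _merge_runs(env > thr, max_gap):
            if (stop - start) / rate >= min_dur:
                onsets[ch_id] = start / rate
                break
    if len(onsets) < 2:
        raise RuntimeError("onset detected on fewer than two channels")
    t0 = min(onsets.values())
    latencies = {ch: t - t0 for ch, t in onsets.items()}
    ordering = sorted(latencies, key=lambda ch: (latencies[ch], ch))
    return latencies, ordering


def match_event_times(
    detected_times: np.ndarray,
    truth_times: np.ndarray,
    tolerance_s: float = 0.010,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to ground-truth event times.

    Returns (n_matched, n_false_positive, n_missed).
    """
    det = sorted(detected_times)
    truth = list(np.sort(np.asarray(truth_times, dtype=float)))
    matched = 0
    for t in det:
        best = None
        for i, g in enumerate(truth):
            if abs(g - t) <= tolerance_s and (
                best is None or abs(g - t) < abs(truth[best] - t)
            ):
                best = i
        if best is not None:
            truth.pop(best)
            matched += 1
    return matched, len(det) - matched, len(truth)
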