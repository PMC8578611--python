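"""Seeded synthetic multichannel LFP generator with ground truth.

Emulates what a 3D microelectrode array records from epileptiform tissue:

* a baseline of mixed white + 1/f noise whose mean windowed peak-to-peak
  amplitude is calibrated to a configurable level (20 µV by default, the
  in-vitro baseline of the device being modelled);
* ictal bursts — an ~80 Hz carrier under a raised-cosine envelope reaching
  millivolt-scale peak-to-peak amplitudes — whose onset at each channel is
  delayed by distance-from-focus / propagation speed, so that seizure
  propagation across the array is encoded in the ground truth;
* high-frequency-oscillation events (ripple 80-250 Hz, fast ripple
  250-500 Hz) as Gaussian-windowed sinusoids (Gabor atoms) on chosen
  channels;
* optional biphasic extracellular spikes.

Everything is driven by one integer seed; the same (layout, config,
schedule, seed) always reproduces the recording bit for bit, and the
event waveforms are purely deterministic, so recording minus the
noise-only run recovers them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArrayLayout",
    "RecordingConfig",
    "IctalBurst",
    "HfoEvent",
    "SpikeEvent",
    "EventSchedule",
    "ArrayRecording",
    "generate_noise",
    "synth_hfo_atom",
    "generate_recording",
    "windowed_p2p_mean",
]

GROUND_TRUTH_COLUMNS = ["channel_id", "type", "time_s", "duration_s", "peak_v", "band"]

RIPPLE_RANGE = (80.0, 250.0)
FAST_RIPPLE_RANGE = (250.0, 500.0)


@dataclass(frozen=True)
class ArrayLayout:
    """Electrode positions on the substrate (µm)."""

    channel_ids: tuple[int, ...]
    positions_um: tuple[tuple[float, float], ...]
    pitch_um: float

    def __post_init__(self) -> None:
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        if len(self.channel_ids) != len(self.positions_um):
            raise ValueError("one position per channel required")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be > 0")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @classmethod
    def grid(cls, n_rows: int, n_cols: int, pitch_um: float) -> "ArrayLayout":
        """Regular grid, channels numbered row-major from the origin corner."""
        ids = tuple(range(n_rows * n_cols))
        pos = tuple(
            (c * pitch_um, r * pitch_um) for r in range(n_rows) for c in range(n_cols)
        )
        return cls(channel_ids=ids, positions_um=pos, pitch_um=pitch_um)

    @classmethod
    def strip(cls, n_channels: int, pitch_um: float) -> "ArrayLayout":
        """Linear strip along x, channel 0 at the origin."""
        ids = tuple(range(n_channels))
        pos = tuple((i * pitch_um, 0.0) for i in range(n_channels))
        return cls(channel_ids=ids, positions_um=pos, pitch_um=pitch_um)


@dataclass(frozen=True)
class RecordingConfig:
    """Sampling and noise settings.

    The default 2 kHz rate keeps the 250-500 Hz fast-ripple band strictly
    below Nyquist; 1 kHz can be selected to mirror hardware that samples
    there, at the cost of the fast-ripple band ending exactly at Nyquist.
    ``noise_p2p`` is the target mean peak-to-peak amplitude of the baseline
    over 100 ms windows, in volts.
    """

    sampling_rate_hz: float = 2000.0
    duration_s: float = 10.0
    noise_p2p: float = 20e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate_hz and duration_s must be > 0")
        if self.noise_p2p < 0:
            raise ValueError("noise_p2p must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.duration_s))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class IctalBurst:
    """One seizure-like burst; ``amplitude_p2p`` is the plateau
    peak-to-peak amplitude in volts (so the carrier peak is half of it)."""

    start_s: float
    end_s: float
    carrier_hz: float = 80.0
    amplitude_p2p: float = 3.2e-3
    ramp_s: float = 0.1  # raised-cosine onset/offset

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("burst end must be after start")
        if self.carrier_hz <= 0 or self.amplitude_p2p < 0 or self.ramp_s < 0:
            raise ValueError("invalid burst parameters")


@dataclass(frozen=True)
class HfoEvent:
    channel_id: int
    time_s: float       # atom centre
    center_freq_hz: float
    duration_s: float
    amplitude: float    # peak, volts

    def __post_init__(self) -> None:
        if self.center_freq_hz <= 0 or self.duration_s <= 0 or self.amplitude < 0:
            raise ValueError("invalid HFO event parameters")


@dataclass(frozen=True)
class SpikeEvent:
    channel_id: int
    time_s: float
    amplitude: float    # peak of negative lobe, volts
    width_s: float = 1e-3


@dataclass(frozen=True)
class EventSchedule:
    """What happens when and where during the recording."""

    ictal_bursts: tuple[IctalBurst, ...] = ()
    hfo_events: tuple[HfoEvent, ...] = ()
    spike_events: tuple[SpikeEvent, ...] = ()
    focus_um: tuple[float, float] = (0.0, 0.0)
    propagation_speed_um_s: float = 1e4

    def __post_init__(self) -> None:
        if self.propagation_speed_um_s <= 0:
            raise ValueError("propagation_speed_um_s must be > 0")


@dataclass(frozen=True)
class ArrayRecording:
    """Multichannel recording (volts) plus the injected ground truth."""

    layout: ArrayLayout
    config: RecordingConfig
    samples: np.ndarray           # (n_channels, n_samples)
    ground_truth: pd.DataFrame    # GROUND_TRUTH_COLUMNS

    def __post_init__(self) -> None:
        expected = (self.layout.n_channels, self.config.n_samples)
        if self.samples.shape != expected:
            raise ValueError(f"samples shape {self.samples.shape} != {expected}")

    def channel(self, channel_id: int) -> np.ndarray:
        return self.samples[self.layout.channel_ids.index(channel_id)]


def windowed_p2p_mean(series: np.ndarray, rate_hz: float, window_s: float = 0.1) -> float:
    """Mean peak-to-peak amplitude over non-overlapping windows."""
    w = max(1, int(round(window_s * rate_hz)))
    n_win = len(series) // w
    if n_win == 0:
        raise ValueError("series shorter than one window")
    x = np.asarray(series[: n_win * w]).reshape(n_win, w)
    return float(np.mean(x.max(axis=1) - x.min(axis=1)))


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    weights = np.zeros_like(f)
    weights[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spectrum * weights, n)
    return x / x.std()


def generate_noise(config: RecordingConfig, n_channels: int) -> np.ndarray:
    """Baseline noise matrix (n_channels x n_samples), calibrated so each
    channel's mean 100 ms-windowed peak-to-peak equals ``config.noise_p2p``.

    The spectrum is an equal-power mix of white and 1/f noise, a reasonable
    stand-in for LFP baselines recorded in saline.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    out = np.empty((n_channels, n))
    for ch in range(n_channels):
        white = rng.standard_normal(n)
        pink = _pink_noise(rng, n)
        x = (white / white.std() + pink) / np.sqrt(2.0)
        if config.noise_p2p == 0:
            out[ch] = 0.0
            continue
        out[ch] = x * (config.noise_p2p / windowed_p2p_mean(x, config.sampling_rate_hz))
    return out


def synth_hfo_atom(
    center_freq: float, duration: float, amplitude: float, rate: float
) -> np.ndarray:
    """Gaussian-windowed sinusoid (Gabor atom) sampled at ``rate``.

    The atom spans ``duration`` seconds with the Gaussian sigma at 1/6 of
    the span, peaks exactly at ``amplitude`` in the centre, and must
    contain at least 4 carrier cycles to count as an oscillation.
    """
    if center_freq >= rate / 2.0:
        raise ValueError("center frequency must be below Nyquist")
    if center_freq * duration < 4.0:
        raise ValueError("atom must contain at least 4 cycles")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    t0 = t[n // 2]
    sigma = duration / 6.0
    return amplitude * np.exp(-0.5 * ((t - t0) / sigma) ** 2) * np.cos(
        2.0 * np.pi * center_freq * (t - t0)
    )


def _hfo_band_name(freq: float) -> str:
    if RIPPLE_RANGE[0] <= freq < RIPPLE_RANGE[1]:
        return "ripple"
    if FAST_RIPPLE_RANGE[0] <= freq <= FAST_RIPPLE_RANGE[1]:
        return "fast_ripple"
    return ""


def _burst_waveform(burst: IctalBurst, onset_s: float, t: np.ndarray) -> np.ndarray:
    """Carrier under a raised-cosine envelope, shifted to this channel's onset."""
    dur = burst.end_s - burst.start_s
    tau = t - onset_s
    env = np.zeros_like(t)
    ramp = min(burst.ramp_s, dur / 2.0)
    inside = (tau >= 0) & (tau <= dur)
    env[inside] = 1.0
    if ramp > 0:
        rising = inside & (tau < ramp)
        env[rising] = 0.5 * (1.0 - np.cos(np.pi * tau[rising] / ramp))
        falling = inside & (tau > dur - ramp)
        env[falling] = 0.5 * (1.0 - np.cos(np.pi * (dur - tau[falling]) / ramp))
    amp = burst.amplitude_p2p / 2.0
    return amp * env * np.sin(2.0 * np.pi * burst.carrier_hz * tau)


def _spike_waveform(spike: SpikeEvent, t: np.ndarray) -> np.ndarray:
    """Biphasic extracellular spike: sharp negative lobe, smaller positive
    rebound, built from two Gaussians."""
    tau = t - spike.time_s
    w = spike.width_s
    neg = np.exp(-0.5 * (tau / (0.25 * w)) ** 2)
    pos = 0.4 * np.exp(-0.5 * ((tau - 0.7 * w) / (0.4 * w)) ** 2)
    return spike.amplitude * (pos - neg)


def generate_recording(
    layout: ArrayLayout,
    config: RecordingConfig,
    schedule: EventSchedule,
) -> ArrayRecording:
    """Noise plus scheduled events, with per-event ground truth.

    Ictal bursts are delayed per channel by distance-to-focus divided by
    the propagation speed; each channel's onset is a ground-truth row of
    type ``onset``.  HFO atoms and spikes land on their scheduled channel
    only.  Frequencies at or above Nyquist are rejected.
    """
    nyquist = config.sampling_rate_hz / 2.0
    for ev in schedule.hfo_events:
        if ev.center_freq_hz >= nyquist:
            raise ValueError("HFO centre frequency at or above Nyquist")
    for burst in schedule.ictal_bursts:
        if burst.carrier_hz >= nyquist:
            raise ValueError("burst carrier at or above Nyquist")

    samples = generate_noise(config, layout.n_channels)
    t = config.times()
    truth_rows: list[tuple] = []

    positions = np.asarray(layout.positions_um, dtype=float)
    focus = np.asarray(schedule.focus_um, dtype=float)
    delays = np.hypot(*(positions - focus).T) / schedule.propagation_speed_um_s

    for burst in schedule.ictal_bursts:
        for ch_idx, ch_id in enumerate(layout.channel_ids):
            onset = burst.start_s + delays[ch_idx]
            samples[ch_idx] += _burst_waveform(burst, onset, t)
            truth_rows.append(
                (ch_id, "onset", onset, burst.end_s - burst.start_s,
                 burst.amplitude_p2p / 2.0, "")
            )

    for ev in schedule.hfo_events:
        ch_idx = layout.channel_ids.index(ev.channel_id)
        atom = synth_hfo_atom(
            ev.center_freq_hz, ev.duration_s, ev.amplitude, config.sampling_rate_hz
        )
        start = int(round((ev.time_s - ev.duration_s / 2.0) * config.sampling_rate_hz))
        lo, hi = max(0, start), min(config.n_samples, start + len(atom))
        samples[ch_idx, lo:hi] += atom[lo - start : hi - start]
        band = _hfo_band_name(ev.center_freq_hz)
        truth_rows.append(
            (ev.channel_id, f"hfo_{band}" if band else "hfo", ev.time_s,
             ev.duration_s, ev.amplitude, band)
        )

    for spike in schedule.spike_events:
        ch_idx = layout.channel_ids.index(spike.channel_id)
        mask = np.abs(t - spike.time_s) < 5.0 * spike.width_s
        samples[ch_idx, mask] += _spike_waveform(spike, t[mask])
        truth_rows.append(
            (spike.channel_id, "spike", spike.time_s, spike.width_s,
             spike.amplitude, "")
        )

    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return ArrayRecording(layout=layout, config=config, samples=samples,
                          ground_truth=truth)
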