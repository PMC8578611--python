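"""Canonical array layouts and recording scenarios.

Two presets mirror the experimental configurations the simulator is built
around:

* ``in_vitro`` — an 8 x 8 grid at 500 µm pitch (the slice-recording MEA),
  ~20 µV baseline, one 80 Hz ictal burst reaching 3.2 mV peak-to-peak
  that propagates from a corner focus, plus ripple and fast-ripple atoms.
* ``in_vivo`` — an 8-channel strip at 350 µm pitch (the flexible cortical
  implant), one 0.5 mV peak-to-peak burst (SNR of order tens) and HFO
  atoms on two channels.

Both default to 2 kHz sampling so the fast-ripple band stays below
Nyquist; pass ``sampling_rate_hz=1000`` to mirror hardware that samples
at 1 kHz.
"""

from __future__ import annotations

from .synth import (
    ArrayLayout,
    EventSchedule,
    HfoEvent,
    IctalBurst,
    RecordingConfig,
)

__all__ = [
    "in_vitro_layout",
    "in_vivo_layout",
    "in_vitro_scenario",
    "in_vivo_scenario",
]


def in_vitro_layout() -> ArrayLayout:
    return ArrayLayout.grid(8, 8, pitch_um=500.0)


def in_vivo_layout() -> ArrayLayout:
    return ArrayLayout.strip(8, pitch_um=350.0)


def in_vitro_scenario(
    seed: int = 0, duration_s: float = 10.0, sampling_rate_hz: float = 2000.0
) -> tuple[ArrayLayout, RecordingConfig, EventSchedule]:
    layout = in_vitro_layout()
    config = RecordingConfig(
        sampling_rate_hz=sampling_rate_hz,
        duration_s=duration_s,
        noise_p2p=20e-6,
        seed=seed,
    )
    schedule = EventSchedule(
        ictal_bursts=(
            IctalBurst(start_s=3.0, end_s=5.0, carrier_hz=80.0, amplitude_p2p=3.2e-3),
        ),
        hfo_events=(
            HfoEvent(channel_id=0, time_s=6.5, center_freq_hz=120.0,
                     duration_s=0.05, amplitude=100e-6),
            HfoEvent(channel_id=9, time_s=7.0, center_freq_hz=400.0,
                     duration_s=0.02, amplitude=100e-6),
        ),
        focus_um=(0.0, 0.0),
        propagation_speed_um_s=1e4,
    )
    return layout, config, schedule


def in_vivo_scenario(
    seed: int = 0, duration_s: float = 10.0, sampling_rate_hz: float = 2000.0
) -> tuple[ArrayLayout, RecordingConfig, EventSchedule]:
    layout = in_vivo_layout()
    config = RecordingConfig(
        sampling_rate_hz=sampling_rate_hz,
        duration_s=duration_s,
        noise_p2p=20e-6,
        seed=seed,
    )
    schedule = EventSchedule(
        ictal_bursts=(
            IctalBurst(start_s=4.0, end_s=6.0, carrier_hz=80.0, amplitude_p2p=0.5e-3),
        ),
        hfo_events=(
            HfoEvent(channel_id=2, time_s=7.0, center_freq_hz=150.0,
                     duration_s=0.05, amplitude=80e-6),
            HfoEvent(channel_id=5, time_s=7.5, center_freq_hz=350.0,
                     duration_s=0.025, amplitude=80e-6),
        ),
        focus_um=(0.0, 0.0),
        propagation_speed_um_s=1e4,
    )
    return layout, config, schedule
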