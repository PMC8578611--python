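"""File formats tying the simulator and the analysis together.

Recordings travel as HDF5 (``/samples`` in volts, ``/time`` in seconds,
sampling rate / seed / provenance as root attributes), channel maps and
event tables as plain CSV.  Every file written carries the tool version,
a hash of the run configuration, and the seed, so a run can be
reproduced bit for bit from its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .synth import (
    GROUND_TRUTH_COLUMNS,
    ArrayLayout,
    ArrayRecording,
    RecordingConfig,
)

__all__ = [
    "config_hash",
    "write_recording",
    "read_recording",
    "write_channel_map",
    "write_events_csv",
    "write_summary_json",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(seed: int, cfg_hash: str) -> dict:
    return {"tool_version": __version__, "config_hash": cfg_hash, "seed": seed}


def write_recording(
    path: str | Path, recording: ArrayRecording, cfg_hash: str = ""
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=recording.samples)
        f.create_dataset("time", data=recording.config.times())
        f.attrs["sampling_rate_hz"] = recording.config.sampling_rate_hz
        f.attrs["noise_p2p_v"] = recording.config.noise_p2p
        f.attrs["seed"] = recording.config.seed
        f.attrs["tool_version"] = __version__
        f.attrs["config_hash"] = cfg_hash
        f.attrs["channel_ids"] = np.asarray(recording.layout.channel_ids)
        f.attrs["positions_um"] = np.asarray(recording.layout.positions_um)
        f.attrs["pitch_um"] = recording.layout.pitch_um


def read_recording(path: str | Path) -> ArrayRecording:
    with h5py.File(path, "r") as f:
        samples = f["samples"][...]
        rate = float(f.attrs["sampling_rate_hz"])
        seed = int(f.attrs["seed"])
        noise = float(f.attrs.get("noise_p2p_v", 0.0))
        ids = tuple(int(i) for i in f.attrs["channel_ids"])
        pos = tuple((float(x), float(y)) for x, y in f.attrs["positions_um"])
        pitch = float(f.attrs["pitch_um"])
    layout = ArrayLayout(channel_ids=ids, positions_um=pos, pitch_um=pitch)
    config = RecordingConfig(
        sampling_rate_hz=rate,
        duration_s=samples.shape[1] / rate,
        noise_p2p=noise,
        seed=seed,
    )
    truth = pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
    return ArrayRecording(layout=layout, config=config, samples=samples,
                          ground_truth=truth)


def write_channel_map(path: str | Path, layout: ArrayLayout) -> None:
    df = pd.DataFrame(
        {
            "channel_id": layout.channel_ids,
            "x_um": [p[0] for p in layout.positions_um],
            "y_um": [p[1] for p in layout.positions_um],
        }
    )
    df.to_csv(path, index=False)


def write_events_csv(path: str | Path, events: pd.DataFrame) -> None:
    """Event table CSV with amplitudes converted to microvolts."""
    out = events.copy()
    out["peak_uv"] = out.pop("peak_v") * 1e6
    out = out[["channel_id", "type", "time_s", "duration_s", "peak_uv", "band"]]
    out.to_csv(path, index=False)


def write_summary_json(
    path: str | Path, payload: dict, seed: int, cfg_hash: str
) -> None:
    payload = dict(payload)
    payload["provenance"] = _provenance(seed, cfg_hash)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
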