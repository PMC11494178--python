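"""Recording container and on-disk formats.

Recordings are stored as raw little-endian float32 binary (sample-major,
``n_samples x n_channels``) next to a JSON sidecar holding the sampling
rate and channel names.  Event tables (cues, movement onsets, clicks,
session logs) are plain CSV with columns ``time_ms, event_type, detail``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["time_ms", "event_type", "detail"]


@dataclass
class Recording:
    """Multichannel raw voltage trace.

    data : (n_samples, n_channels) float array
    fs_hz : sampling rate in Hz
    channel_names : one name per column
    """

    data: np.ndarray
    fs_hz: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (samples x channels)")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def save(self, path: str | Path) -> None:
        """Write ``<path>.dat`` (float32 raw) and ``<path>.json`` (sidecar)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        raw = path.with_suffix(".dat")
        self.data.astype("<f4").tofile(raw)
        meta = {
            "format": "bciclick-raw-v1",
            "dtype": "<f4",
            "order": "sample-major",
            "n_samples": self.n_samples,
            "n_channels": self.n_channels,
            "fs_hz": self.fs_hz,
            "channel_names": self.channel_names,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta.get("format") != "bciclick-raw-v1":
            raise ValueError(f"unrecognized recording format: {meta.get('format')}")
        data = np.fromfile(path.with_suffix(".dat"), dtype=meta["dtype"])
        data = data.reshape(meta["n_samples"], meta["n_channels"]).astype(np.float64)
        return cls(data=data, fs_hz=meta["fs_hz"], channel_names=meta["channel_names"])


def write_events(events: pd.DataFrame | list[tuple], path: str | Path) -> None:
    """Write an event table (time_ms, event_type, detail) as CSV."""
    if not isinstance(events, pd.DataFrame):
        events = pd.DataFrame(events, columns=EVENT_COLUMNS)
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df
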