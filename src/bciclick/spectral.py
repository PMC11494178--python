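"""Per-100 ms calibration-normalized high-gamma features.

A 256 ms window is slid in 100 ms steps over each channel; the windowed
FFT power in each frequency bin is log-transformed, z-scored against
resting-calibration statistics, and the z-scores of the 110-170 Hz bins
are summed into one high-gamma value per channel.  Batch extraction and
packetized streaming produce bit-identical frames.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import Recording

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-30  # guards log(0) on degenerate all-zero windows


@dataclass
class SpectralConfig:
    fs_hz: float = 1000.0
    window_ms: float = 256.0
    step_ms: float = 100.0
    hg_low_hz: float = 110.0
    hg_high_hz: float = 170.0
    taper: str = "hann"  # or "rectangular"
    sd_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.hg_high_hz >= self.fs_hz / 2.0:
            raise ValueError("high-gamma band must lie below Nyquist")
        if self.hg_low_hz >= self.hg_high_hz:
            raise ValueError("hg_low_hz must be below hg_high_hz")
        if abs(self.window_samples - self.window_ms * self.fs_hz / 1000.0) > 1e-9:
            raise ValueError("window_ms must be an integer number of samples")
        if self.taper not in ("hann", "rectangular"):
            raise ValueError("taper must be 'hann' or 'rectangular'")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.fs_hz / 1000.0))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_ms * self.fs_hz / 1000.0))

    @property
    def bin_freqs_hz(self) -> np.ndarray:
        return np.fft.rfftfreq(self.window_samples, d=1.0 / self.fs_hz)

    @property
    def hg_bins(self) -> np.ndarray:
        """Indices of bins whose center frequency lies in [low, high], inclusive."""
        f = self.bin_freqs_hz
        return np.nonzero((f >= self.hg_low_hz) & (f <= self.hg_high_hz))[0]

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.window_samples:
            return 0
        return (n_samples - self.window_samples) // self.step_samples + 1


@dataclass
class CalibrationStats:
    """Per-(channel, bin) mean and SD of resting log-power."""

    mean: np.ndarray  # (n_channels, n_bins)
    sd: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean/sd shape mismatch")

    def save(self, path) -> None:
        np.savez(path, mean=self.mean, sd=self.sd, n_frames=self.n_frames)

    @classmethod
    def load(cls, path) -> "CalibrationStats":
        z = np.load(path)
        return cls(mean=z["mean"], sd=z["sd"], n_frames=int(z["n_frames"]))


@dataclass
class FeatureFrame:
    """One normalized high-gamma vector; ``t_ms`` is the window's right edge."""

    t_ms: float
    hg: np.ndarray  # (n_channels,)


def _taper(cfg: SpectralConfig) -> np.ndarray:
    if cfg.taper == "hann":
        return sps.get_window("hann", cfg.window_samples, fftbins=True)
    return np.ones(cfg.window_samples)


def frame_logpower(segment: np.ndarray, cfg: SpectralConfig) -> np.ndarray:
    """Log FFT power of one window. ``segment``: (window_samples, n_channels).

    Returns (n_channels, n_bins).
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 2 or segment.shape[0] != cfg.window_samples:
        raise ValueError(
            f"segment must be ({cfg.window_samples}, n_channels), got {segment.shape}"
        )
    if not np.all(np.isfinite(segment)):
        raise ValueError("segment contains non-finite samples")
    spec = np.fft.rfft(segment * _taper(cfg)[:, None], axis=0)
    power = np.abs(spec) ** 2
    return np.log(np.maximum(power.T, _LOG_FLOOR))


def _iter_windows(data: np.ndarray, cfg: SpectralConfig):
    n = cfg.n_frames(data.shape[0])
    w, s = cfg.window_samples, cfg.step_samples
    for i in range(n):
        yield i * s + w, data[i * s : i * s + w]


def fit_calibration(recording: Recording, cfg: SpectralConfig) -> CalibrationStats:
    """Resting-baseline log-power statistics at the standard 100 ms cadence."""
    data = recording.data
    n = cfg.n_frames(data.shape[0])
    if n < 1:
        raise ValueError("calibration recording shorter than one analysis window")
    acc = np.zeros((n, data.shape[1], len(cfg.bin_freqs_hz)))
    for i, (_, seg) in enumerate(_iter_windows(data, cfg)):
        acc[i] = frame_logpower(seg, cfg)
    mean = acc.mean(axis=0)
    sd = acc.std(axis=0)
    n_floored = int(np.sum(sd < cfg.sd_floor))
    if n_floored:
        warnings.warn(
            f"{n_floored} (channel, bin) pairs had calibration SD below "
            f"{cfg.sd_floor}; floor applied",
            stacklevel=2,
        )
        logger.warning("calibration SD floored on %d (channel, bin) pairs", n_floored)
    return CalibrationStats(mean=mean, sd=np.maximum(sd, cfg.sd_floor), n_frames=n)


def hg_feature(logpower: np.ndarray, calib: CalibrationStats, cfg: SpectralConfig) -> np.ndarray:
    """Sum of z-scored in-band bin log-powers, one value per channel."""
    if logpower.shape != calib.mean.shape:
        raise ValueError("logpower shape does not match calibration stats")
    z = (logpower - calib.mean) / calib.sd
    return z[:, cfg.hg_bins].sum(axis=1)


def stream_features(
    signal: np.ndarray | Recording, calib: CalibrationStats, cfg: SpectralConfig
) -> list[FeatureFrame]:
    """Extract the ordered frame sequence for a whole recording."""
    data = signal.data if isinstance(signal, Recording) else np.asarray(signal)
    if cfg.n_frames(data.shape[0]) < 1:
        raise ValueError("signal shorter than one analysis window")
    frames = []
    for edge, seg in _iter_windows(data, cfg):
        hg = hg_feature(frame_logpower(seg, cfg), calib, cfg)
        frames.append(FeatureFrame(t_ms=edge / cfg.fs_hz * 1000.0, hg=hg))
    return frames


class StreamingExtractor:
    """Packetized front end: feed arbitrary sample packets, collect frames.

    Maintains the 256 ms running buffer; a frame is emitted every time a
    full window ending on the 100 ms grid becomes available, so output is
    identical to :func:`stream_features` on the concatenated signal.
    """

    def __init__(self, calib: CalibrationStats, cfg: SpectralConfig):
        self.calib = calib
        self.cfg = cfg
        self._buf: list[np.ndarray] = []
        self._buffered = 0  # samples currently in _buf
        self._consumed = 0  # samples dropped from the front of the stream

    def push(self, packet: np.ndarray) -> list[FeatureFrame]:
        packet = np.atleast_2d(np.asarray(packet, dtype=np.float64))
        self._buf.append(packet)
        self._buffered += packet.shape[0]
        cfg = self.cfg
        w, s = cfg.window_samples, cfg.step_samples
        out: list[FeatureFrame] = []
        while self._buffered >= w:
            data = np.concatenate(self._buf, axis=0) if len(self._buf) > 1 else self._buf[0]
            self._buf = [data]
            seg = data[:w]
            edge = self._consumed + w
            hg = hg_feature(frame_logpower(seg, cfg), self.calib, cfg)
            out.append(FeatureFrame(t_ms=edge / cfg.fs_hz * 1000.0, hg=hg))
            self._buf = [data[s:]]
            self._buffered -= s
            self._consumed += s
        return out


def frames_to_array(frames: list[FeatureFrame]) -> tuple[np.ndarray, np.ndarray]:
    """(t_ms vector, (n_frames, n_channels) matrix) from a frame list."""
    t = np.array([f.t_ms for f in frames])
    X = np.stack([f.hg for f in frames])
    return t, X
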