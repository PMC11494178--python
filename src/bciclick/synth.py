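"""Synthetic multichannel ECoG with event-related high-gamma modulation.

The generator emulates the statistical structure the decoding pipeline
assumes: a 1/f-shaped Gaussian background on every channel, multiplicative
110-170 Hz band power increases on a subset of "hand" channels time-locked
to movement onsets (cue time + a per-trial uniform reaction delay), Go-cue
timelines with uniformly jittered inter-stimulus intervals, an optional
low-frequency ERD-then-ERS confound, and a behavioral user model for
closed-loop switch-scan spelling.

Grasp modulation is band-limited Gaussian noise scaled so that in-band
power during the burst equals ``hg_effect**2`` times the resting in-band
power, with 50 ms cosine on/off ramps.  The per-trial reaction delay moves
the whole burst on every hand channel identically, so shift-only time
warping can recover it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import Recording

# Paul Kellet's economy pinking filter: white noise -> approximately 1/f
# amplitude spectrum.  Fixed coefficients, applied per channel with
# persistent state so chunked generation is continuous.
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])

HAND_KNOB_CHANNELS = (92, 93, 94, 100, 101, 102, 108, 109, 110, 116, 117, 118)


def _iir_band_power(b, a, lo_hz: float, hi_hz: float, fs_hz: float) -> float:
    """Integral of |H(f)|^2 over [lo, hi] for unit-variance white input."""
    w, h = sps.freqz(b, a, worN=8192, fs=fs_hz)
    m = (w >= lo_hz) & (w <= hi_hz)
    return float(np.trapezoid(np.abs(h[m]) ** 2, w[m]))


def _sos_band_power(sos, lo_hz: float, hi_hz: float, fs_hz: float) -> float:
    w, h = sps.sosfreqz(sos, worN=8192, fs=fs_hz)
    m = (w >= lo_hz) & (w <= hi_hz)
    return float(np.trapezoid(np.abs(h[m]) ** 2, w[m]))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic recordings.

    ``hg_effect`` is the multiplicative in-band (110-170 Hz) *amplitude*
    gain during a grasp burst, so in-band power rises by ``hg_effect**2``.
    """

    n_channels: int = 128
    fs_hz: float = 1000.0
    hand_channels: tuple[int, ...] = HAND_KNOB_CHANNELS
    hg_effect: float = 2.0
    hg_band_hz: tuple[float, float] = (110.0, 170.0)
    burst_duration_ms: float = 800.0
    ramp_ms: float = 50.0
    reaction_delay_bounds_ms: tuple[float, float] = (150.0, 450.0)
    isi_bounds_ms: tuple[float, float] = (3000.0, 4500.0)
    t_go_ms: float = 100.0
    lf_confound: bool = False
    lf_band_hz: tuple[float, float] = (10.0, 30.0)
    lf_strength: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hg_effect < 1.0:
            # == 1 is the null condition (no modulation at all)
            raise ValueError("hg_effect must be >= 1 (amplitude gain during grasp)")
        if self.fs_hz / 2.0 <= self.hg_band_hz[1]:
            raise ValueError("Nyquist frequency must exceed the high-gamma band")
        if any(c < 0 or c >= self.n_channels for c in self.hand_channels):
            raise ValueError("hand_channels out of range")
        if self.isi_bounds_ms[0] > self.isi_bounds_ms[1]:
            raise ValueError("isi_bounds_ms must be (min, max)")
        if self.isi_bounds_ms[0] < self.burst_duration_ms + self.reaction_delay_bounds_ms[1] + 500.0:
            raise ValueError("minimum ISI too short for the burst plus label margins")


@dataclass
class GroundTruth:
    """Cue and movement timing that real studies recover from video."""

    cue_onsets_ms: list[float] = field(default_factory=list)
    movement_onsets_ms: list[float] = field(default_factory=list)
    per_trial_delay_ms: list[float] = field(default_factory=list)
    intended_click_times_ms: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cue_onsets_ms) != len(self.movement_onsets_ms):
            raise ValueError("cue and movement onset lists must align")
        for c, m in zip(self.cue_onsets_ms, self.movement_onsets_ms):
            if m < c:
                raise ValueError("movement onset precedes its cue")


class StreamingSynth:
    """Chunked signal generator with persistent filter state.

    ``next_chunk`` produces the next ``n`` samples of every channel;
    ``add_grasp`` queues a high-gamma burst (and, with the confound
    enabled, an ERD/ERS low-frequency excursion) starting at a given
    absolute time.  Bursts may be queued before or during generation as
    long as they start at or after the current stream position.
    """

    def __init__(self, cfg: SynthConfig, seed: int | None = None):
        self.cfg = cfg
        root = np.random.default_rng(cfg.seed if seed is None else seed)
        self._bg_rng, self._burst_rng, self._lf_rng = root.spawn(3)
        self._pos = 0  # absolute sample index of the next sample to emit
        self._bg_zi = np.zeros((max(len(_PINK_A), len(_PINK_B)) - 1, cfg.n_channels))
        # burst scaling: added in-band power = (hg^2 - 1) * resting in-band power
        lo, hi = cfg.hg_band_hz
        self._burst_sos = sps.butter(4, [lo, hi], btype="band", fs=cfg.fs_hz, output="sos")
        p_rest = _iir_band_power(_PINK_B, _PINK_A, lo, hi, cfg.fs_hz)
        p_unit = _sos_band_power(self._burst_sos, lo, hi, cfg.fs_hz)
        self._burst_gain = np.sqrt((cfg.hg_effect**2 - 1.0) * p_rest / p_unit)
        # pending additive components: list of (start_sample, (len, n_hand) array)
        self._pending: list[tuple[int, np.ndarray]] = []
        if cfg.lf_confound:
            llo, lhi = cfg.lf_band_hz
            self._lf_sos = sps.butter(4, [llo, lhi], btype="band", fs=cfg.fs_hz, output="sos")
            p_rest_lf = _iir_band_power(_PINK_B, _PINK_A, llo, lhi, cfg.fs_hz)
            p_unit_lf = _sos_band_power(self._lf_sos, llo, lhi, cfg.fs_hz)
            self._lf_gain = cfg.lf_strength * np.sqrt(p_rest_lf / p_unit_lf)
            self._lf_zi = np.zeros((self._lf_sos.shape[0], 2, len(cfg.hand_channels)))
            self._lf_events: list[int] = []
        # wash out the filter startup transient
        self._prime(int(0.5 * cfg.fs_hz))

    def _prime(self, n: int) -> None:
        white = self._bg_rng.standard_normal((n, self.cfg.n_channels))
        _, self._bg_zi = sps.lfilter(_PINK_B, _PINK_A, white, axis=0, zi=self._bg_zi)
        if self.cfg.lf_confound:
            w = self._lf_rng.standard_normal((n, len(self.cfg.hand_channels)))
            _, self._lf_zi = sps.sosfilt(self._lf_sos, w, axis=0, zi=self._lf_zi)

    @property
    def t_ms(self) -> float:
        """Absolute time of the next sample to be generated."""
        return self._pos / self.cfg.fs_hz * 1000.0

    def _burst_waveform(self) -> np.ndarray:
        cfg = self.cfg
        n = int(round(cfg.burst_duration_ms * cfg.fs_hz / 1000.0))
        pad = int(0.2 * cfg.fs_hz)
        white = self._burst_rng.standard_normal((n + pad, len(cfg.hand_channels)))
        band = sps.sosfilt(self._burst_sos, white, axis=0)[pad:]
        n_ramp = int(round(cfg.ramp_ms * cfg.fs_hz / 1000.0))
        env = np.ones(n)
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
        return self._burst_gain * band * env[:, None]

    def add_grasp(self, t_ms: float) -> None:
        start = int(round(t_ms * self.cfg.fs_hz / 1000.0))
        if start < self._pos:
            raise ValueError("burst start lies before the current stream position")
        self._pending.append((start, self._burst_waveform()))
        if self.cfg.lf_confound:
            self._lf_events.append(start)

    def _lf_profile(self, n: int) -> np.ndarray:
        """Per-sample gain of the low-frequency component for the next chunk."""
        fs = self.cfg.fs_hz
        t = self._pos + np.arange(n)
        g = np.ones(n)
        for m in self._lf_events:
            erd = (t >= m - 0.3 * fs) & (t < m + 0.8 * fs)
            ers = (t >= m + 0.8 * fs) & (t < m + 1.8 * fs)
            g[erd] = 0.2
            g[ers] = 1.8
        return g

    def next_chunk(self, n: int) -> np.ndarray:
        cfg = self.cfg
        white = self._bg_rng.standard_normal((n, cfg.n_channels))
        chunk, self._bg_zi = sps.lfilter(_PINK_B, _PINK_A, white, axis=0, zi=self._bg_zi)
        if cfg.lf_confound:
            w = self._lf_rng.standard_normal((n, len(cfg.hand_channels)))
            lf, self._lf_zi = sps.sosfilt(self._lf_sos, w, axis=0, zi=self._lf_zi)
            lf = lf * self._lf_gain * self._lf_profile(n)[:, None]
            chunk[:, list(cfg.hand_channels)] += lf
        keep = []
        for start, wave in self._pending:
            a = max(start, self._pos)
            b = min(start + len(wave), self._pos + n)
            if a < b:
                chunk[a - self._pos : b - self._pos, list(cfg.hand_channels)] += wave[
                    a - start : b - start
                ]
            if start + len(wave) > self._pos + n:
                keep.append((start, wave))
        self._pending = keep
        self._pos += n
        return chunk

    def generate(self, duration_s: float) -> Recording:
        data = self.next_chunk(int(round(duration_s * self.cfg.fs_hz)))
        return Recording(data=data, fs_hz=self.cfg.fs_hz)


def generate_calibration(cfg: SynthConfig, duration_s: float = 60.0) -> Recording:
    """Stationary rest-state recording with no grasp modulation."""
    if duration_s < 1.0:
        raise ValueError("calibration must span at least 1 s")
    return StreamingSynth(cfg).generate(duration_s)


def make_cue_timeline(cfg: SynthConfig, n_trials: int, rng: np.random.Generator,
                      start_ms: float = 2000.0) -> list[float]:
    """Go-cue onsets spaced by the 100 ms cue plus a uniformly jittered ISI."""
    cues = []
    t = start_ms
    lo, hi = cfg.isi_bounds_ms
    for _ in range(n_trials):
        cues.append(t)
        t += cfg.t_go_ms + rng.uniform(lo, hi)
    return cues


def generate_training_session(
    cfg: SynthConfig, n_trials: int, seed: int | None = None
) -> tuple[Recording, GroundTruth]:
    """Cued-grasp training block: ``n_trials`` bursts on the hand channels.

    Each movement onset is the cue time plus a per-trial reaction delay
    drawn uniformly from ``cfg.reaction_delay_bounds_ms``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seed = cfg.seed if seed is None else seed
    timeline_rng = np.random.default_rng(seed).spawn(1)[0]
    synth = StreamingSynth(cfg, seed=seed)
    cues = make_cue_timeline(cfg, n_trials, timeline_rng)
    lo, hi = cfg.reaction_delay_bounds_ms
    delays = timeline_rng.uniform(lo, hi, size=n_trials)
    onsets = [c + d for c, d in zip(cues, delays)]
    for m in onsets:
        synth.add_grasp(m)
    duration_s = (onsets[-1] + cfg.burst_duration_ms + 2000.0) / 1000.0
    rec = synth.generate(duration_s)
    gt = GroundTruth(
        cue_onsets_ms=cues,
        movement_onsets_ms=onsets,
        per_trial_delay_ms=list(delays),
    )
    return rec, gt


# ---------------------------------------------------------------------------
# Behavioral user model for closed-loop spelling


@dataclass
class UserModelConfig:
    """Stand-in for the participant's click-timing behavior.

    ``reaction_latency_bounds_ms``: delay from target highlight to attempted
    grasp; the default keeps on-screen clicks inside the highlight period at
    the default scan rate.  ``error_rate``: probability of aiming at the
    wrong row/column.  After an erroneous output the user always targets the
    delete keys (task rules).
    """

    reaction_latency_bounds_ms: tuple[float, float] = (150.0, 450.0)
    error_rate: float = 0.0
    corrects_errors: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


def next_target_key(state, prompt: str) -> str:
    """Key id the user should aim for given the typed buffer.

    Wrong output is deleted first (DEL, or A-DEL after a multi-character
    autocompleted insertion); a completed prompt is finalized with ENTER.
    """
    typed = state.typed
    if not prompt.startswith(typed):
        return "A-DEL" if getattr(state, "last_output_len", 1) > 1 else "DEL"
    if typed == prompt:
        return "ENTER"
    return prompt[len(typed)]


def simulate_user(state, prompt: str, cfg: UserModelConfig, rng: np.random.Generator):
    """Decide whether to attempt a grasp during the current scan step.

    Returns ``(intend, offset_ms)``: ``offset_ms`` is the grasp-onset delay
    from the start of the current highlight period.  The user clicks when
    the highlighted row (row-scan) or key (column-scan) leads toward the
    next needed character of the prompt; with probability ``error_rate``
    the aim is displaced to the adjacent row/column.
    """
    target = next_target_key(state, prompt)
    loc = state.layout.locate(target)
    if loc is None:
        raise ValueError(f"prompt requires key {target!r} absent from the layout")
    row, col = loc
    if state.highlight is None:  # pre-selection step
        return False, None
    if rng.uniform() < cfg.error_rate:
        if state.phase == "row":
            row = (row + 1) % state.layout.n_rows
        else:
            col = (col + 1) % state.layout.row_len(state.selected_row)
    if state.phase == "row":
        want = state.highlight == row
    elif state.selected_row != row:
        # wrong row was entered: escape by selecting the first harmless key,
        # then recover through the delete keys
        keys = state.layout.rows[state.selected_row]
        escape = next(c for c, k in enumerate(keys) if k.kind != "enter")
        want = state.highlight == escape
    else:
        want = state.highlight == col
    if not want:
        return False, None
    lo, hi = cfg.reaction_latency_bounds_ms
    return True, float(rng.uniform(lo, hi))
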