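"""Voting-window click detection over the 100 ms classification stream.

Each rest/grasp classification enters a ring buffer of the last ``window``
votes; a click fires as soon as the number of grasp votes reaches the
threshold.  Every click starts a 1 s lock-out during which votes are not
accumulated, and the buffer is cleared on click so a single attempted
grasp cannot re-fire at lock-out expiry.

Latency convention: a classification timestamped ``t`` summarizes the
100 ms packet ending at ``t``, so an all-grasp stream beginning at packet
boundary ``t0`` yields its k-th grasp vote at ``t0 + k*100`` and, with a
4-vote threshold, a click at ``t0 + 400`` — the 400 ms minimum
algorithmic latency.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .labeling import LabelConfig, LabeledFrames, assign_labels
from .model import LSTMClassifier, predict_stream


@dataclass
class VotingConfig:
    window: int = 7
    threshold: int = 4
    lockout_ms: float = 1000.0
    onscreen_delay_ms: float = 200.0
    clear_on_click: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.threshold <= self.window:
            raise ValueError("need 1 <= threshold <= window")
        if self.lockout_ms < 0:
            raise ValueError("lockout_ms must be non-negative")


#: communication-board condition: all 10 of 10 votes must be grasp
BOARD_VOTING = VotingConfig(window=10, threshold=10)
#: speller conditions used online
SPELLER_VOTING_7 = VotingConfig(window=7, threshold=7)
SPELLER_VOTING_4 = VotingConfig(window=7, threshold=4)


@dataclass
class ClickEvent:
    detect_t_ms: float
    onscreen_t_ms: float
    source: str = "offline-sim"

    def __post_init__(self) -> None:
        if self.onscreen_t_ms < self.detect_t_ms:
            raise ValueError("on-screen click cannot precede detection")


@dataclass
class DetectorState:
    votes: deque = field(default_factory=deque)
    lockout_until_ms: float = -np.inf
    last_t_ms: float = -np.inf


def vote_step(
    state: DetectorState, is_grasp: bool | int, t_ms: float, cfg: VotingConfig
) -> ClickEvent | None:
    """Advance the detector by one classification; maybe emit a click."""
    if t_ms <= state.last_t_ms:
        raise ValueError("classification timestamps must be strictly increasing")
    state.last_t_ms = t_ms
    if t_ms < state.lockout_until_ms:
        return None
    state.votes.append(1 if is_grasp else 0)
    while len(state.votes) > cfg.window:
        state.votes.popleft()
    if sum(state.votes) >= cfg.threshold:
        state.lockout_until_ms = t_ms + cfg.lockout_ms
        if cfg.clear_on_click:
            state.votes.clear()
        return ClickEvent(detect_t_ms=t_ms, onscreen_t_ms=t_ms + cfg.onscreen_delay_ms)
    return None


def run_votes(
    labels: np.ndarray, t_ms: np.ndarray, cfg: VotingConfig
) -> list[ClickEvent]:
    """Run the voting detector over a whole classification stream."""
    state = DetectorState()
    clicks = []
    for lab, t in zip(labels, t_ms):
        ev = vote_step(state, lab, float(t), cfg)
        if ev is not None:
            clicks.append(ev)
    return clicks


def run_detector(
    model: LSTMClassifier, X_frames: np.ndarray, frame_t_ms: np.ndarray, cfg: VotingConfig
) -> list[ClickEvent]:
    """predict_stream composed with the voting window; deterministic."""
    labels, _ = predict_stream(model, X_frames)
    return run_votes(labels, np.asarray(frame_t_ms), cfg)


def harvest_training_from_spelling(
    frame_t_ms: np.ndarray,
    movement_onsets_ms,
    onset_s: float = 0.0,
    offset_s: float = 0.8,
    min_separation_ms: float = 3000.0,
    exclusion_pad_ms: tuple[float, float] = (1000.0, 2000.0),
    step_ms: float = 100.0,
) -> tuple[LabeledFrames, np.ndarray]:
    """Labels for model updates built around movement onsets of a spelling log.

    Grasps occurring less than ``min_separation_ms`` (the minimum jittered
    ISI) after the preceding grasp are excluded from training; frames around
    the excluded grasps are dropped entirely (mask returned) rather than
    mislabeled as rest.  The label window is relative to movement onset, not
    a Go cue.

    Returns ``(labeled_frames, keep_mask)``.
    """
    onsets = np.asarray(list(movement_onsets_ms), dtype=float)
    if len(onsets) == 0:
        raise ValueError("session log contains no movement onsets")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("movement onsets must be strictly increasing")
    keep_trial = np.ones(len(onsets), dtype=bool)
    keep_trial[1:] = np.diff(onsets) >= min_separation_ms
    retained = onsets[keep_trial]
    cfg = LabelConfig(
        onset_s=onset_s if onset_s < offset_s else offset_s - 1e-3,
        offset_s=offset_s,
        trial_window_s=(min(-1.0, onset_s), max(2.5, offset_s)),
    )
    labeled = assign_labels(
        np.asarray(frame_t_ms), retained, np.zeros(len(retained)), cfg, step_ms=step_ms
    )
    keep_mask = np.ones(len(frame_t_ms), dtype=bool)
    t = np.asarray(frame_t_ms)
    for m in onsets[~keep_trial]:
        keep_mask &= ~((t >= m - exclusion_pad_ms[0]) & (t <= m + exclusion_pad_ms[1]))
    return labeled, keep_mask
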