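"""Rest/grasp labels from cue timelines via shift-only trial realignment.

Trials are re-aligned by per-trial integer frame shifts (one shift per
trial, applied identically across channels), fit by coordinate ascent
against an iteratively refined cross-trial template.  Grasp labels go to
frames inside a closed onset/offset window around each (shifted) cue;
everything else is rest.  Balanced contiguous folds support leakage-free
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrialTimeline:
    cue_onsets_ms: list[float]
    t_go_ms: float = 100.0
    isi_bounds_ms: tuple[float, float] = (3000.0, 4500.0)

    def __post_init__(self) -> None:
        cues = np.asarray(self.cue_onsets_ms, dtype=float)
        if len(cues) > 1:
            gaps = np.diff(cues)
            if np.any(gaps <= 0):
                raise ValueError("cue onsets must be strictly increasing")
            if np.any(gaps < self.t_go_ms + self.isi_bounds_ms[0] - 1e-9):
                raise ValueError("cue gaps violate the minimum ISI")


@dataclass
class LabelConfig:
    """Grasp-label window relative to the Go cue, in seconds."""

    onset_s: float = 0.3
    offset_s: float = 1.1
    trial_window_s: tuple[float, float] = (-1.0, 2.5)

    def __post_init__(self) -> None:
        if self.onset_s >= self.offset_s:
            raise ValueError("onset must precede offset")
        lo, hi = self.trial_window_s
        if not (lo <= self.onset_s and self.offset_s <= hi):
            raise ValueError("label window must lie inside the trial window")


@dataclass
class ShiftWarpResult:
    shift_frames: np.ndarray  # per-trial integer shifts, 100 ms units
    template: np.ndarray  # (n_frames, n_channels) trial average after alignment
    channels_used: np.ndarray
    converged: bool


@dataclass
class LabeledFrames:
    """Frame-level labels: 1 = grasp, 0 = rest; trial_id -1 outside trials."""

    t_ms: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray


def extract_trial_tensor(
    t_ms: np.ndarray,
    X: np.ndarray,
    cue_onsets_ms,
    window_s: tuple[float, float] = (-1.0, 2.5),
    step_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut cue-aligned segments into a (trials, frames, channels) tensor.

    Returns the tensor and the nominal frame times (ms) relative to the cue.
    """
    t_ms = np.asarray(t_ms)
    n_per = int(round((window_s[1] - window_s[0]) * 1000.0 / step_ms)) + 1
    segs = []
    for cue in cue_onsets_ms:
        start = int(np.searchsorted(t_ms, cue + window_s[0] * 1000.0 - 1e-9))
        if start + n_per > len(t_ms):
            raise ValueError("trial window extends past the end of the recording")
        segs.append(X[start : start + n_per])
    rel = window_s[0] * 1000.0 + np.arange(n_per) * step_ms
    return np.stack(segs), rel


def select_modulated_channels(
    trial_tensor: np.ndarray,
    n_select: int,
    rel_t_ms: np.ndarray | None = None,
    peak_window_s: tuple[float, float] = (0.0, 1.5),
) -> np.ndarray:
    """Top-n channels by trial-averaged peak value after the cue.

    Ties break toward the lowest channel index.
    """
    trials, n_frames, n_channels = trial_tensor.shape
    if trials < 5:
        raise ValueError("need at least 5 trials to rank channel modulation")
    if n_select > n_channels:
        raise ValueError("n_select exceeds channel count")
    if rel_t_ms is None:
        rel_t_ms = np.arange(n_frames) * 100.0
    mean_trace = trial_tensor.mean(axis=0)
    mask = (rel_t_ms > peak_window_s[0] * 1000.0) & (rel_t_ms <= peak_window_s[1] * 1000.0)
    if not mask.any():
        raise ValueError("peak window contains no frames")
    score = mean_trace[mask].max(axis=0)
    order = np.lexsort((np.arange(n_channels), -score))
    return np.sort(order[:n_select])


def _shift_score(trial: np.ndarray, template: np.ndarray, s: int) -> float:
    """Summed per-channel correlation between trial shifted by ``s`` and template."""
    n = trial.shape[0]
    if s >= 0:
        a, b = trial[s:], template[: n - s]
    else:
        a, b = trial[: n + s], template[-s:]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    num = (a * b).sum(axis=0)
    ok = denom > 0
    return float((num[ok] / denom[ok]).sum())


def _apply_shift(trial: np.ndarray, s: int) -> np.ndarray:
    """Edge-replicated shift: aligned[t] = trial[t + s]."""
    n = trial.shape[0]
    idx = np.clip(np.arange(n) + s, 0, n - 1)
    return trial[idx]


def fit_shift_warp(
    trial_tensor: np.ndarray,
    max_shift_frames: int = 5,
    max_iter: int = 50,
    channels_used: np.ndarray | None = None,
) -> ShiftWarpResult:
    """Per-trial integer shifts maximizing agreement with the trial average.

    Coordinate ascent: re-align every trial against the current template,
    recenter the shifts (alignment is identifiable only up to a global
    constant), then re-average.  Converges when no shift changes.
    """
    trials = trial_tensor.shape[0]
    if trials < 2:
        raise ValueError("need at least 2 trials to fit shifts")
    if channels_used is None:
        channels_used = np.arange(trial_tensor.shape[2])
    tensor = trial_tensor[:, :, channels_used]
    shifts = np.zeros(trials, dtype=int)
    candidates = range(-max_shift_frames, max_shift_frames + 1)
    converged = False
    for _ in range(max_iter):
        aligned = np.stack([_apply_shift(tensor[i], shifts[i]) for i in range(trials)])
        total = aligned.sum(axis=0)
        new = np.empty_like(shifts)
        for i in range(trials):
            # leave-one-out template: scoring a trial against an average that
            # contains the trial itself biases every shift toward zero
            template = (total - aligned[i]) / (trials - 1)
            scores = [(s, _shift_score(tensor[i], template, s)) for s in candidates]
            best_s, best = scores[0]
            for s, sc in scores[1:]:
                if sc > best:
                    best_s, best = s, sc
            new[i] = best_s
        new = new - int(np.round(np.median(new)))
        new = np.clip(new, -max_shift_frames, max_shift_frames)
        if np.array_equal(new, shifts):
            converged = True
            break
        shifts = new
    template = np.mean(
        [_apply_shift(trial_tensor[i], shifts[i]) for i in range(trials)], axis=0
    )
    return ShiftWarpResult(
        shift_frames=shifts,
        template=template,
        channels_used=np.asarray(channels_used),
        converged=converged,
    )


def mean_pairwise_correlation(trial_tensor: np.ndarray, shifts: np.ndarray | None = None) -> float:
    """Mean inter-trial correlation of per-trial traces (channel-averaged)."""
    trials = trial_tensor.shape[0]
    if shifts is None:
        shifts = np.zeros(trials, dtype=int)
    traces = np.stack(
        [_apply_shift(trial_tensor[i], int(shifts[i])).mean(axis=1) for i in range(trials)]
    )
    c = np.corrcoef(traces)
    iu = np.triu_indices(trials, k=1)
    return float(np.nanmean(c[iu]))


def estimate_onset_offset(
    trace: np.ndarray,
    rel_t_ms: np.ndarray,
    threshold_fraction: float = 0.5,
    override: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Onset/offset (s, relative to cue) from the aligned trial average.

    First and last crossing of ``threshold_fraction`` of the peak elevation
    above the pre-cue median; a supplied ``override`` is returned verbatim
    (the study pinned these visually).
    """
    if override is not None:
        return override
    trace = np.asarray(trace, dtype=float)
    rest = np.median(trace[rel_t_ms < 0]) if (rel_t_ms < 0).any() else np.median(trace)
    post = rel_t_ms >= 0
    peak = trace[post].max()
    if peak - rest <= 1e-12:
        raise ValueError("flat trace: no modulation peak above the rest median")
    thr = rest + threshold_fraction * (peak - rest)
    above = post & (trace >= thr)
    idx = np.nonzero(above)[0]
    return float(rel_t_ms[idx[0]] / 1000.0), float(rel_t_ms[idx[-1]] / 1000.0)


def assign_labels(
    t_ms: np.ndarray,
    cue_onsets_ms,
    shift_frames,
    label_cfg: LabelConfig,
    step_ms: float = 100.0,
) -> LabeledFrames:
    """Grasp labels on frames in [cue + onset + shift, cue + offset + shift].

    The window is closed on both ends; all other frames are rest.
    """
    t_ms = np.asarray(t_ms)
    cues = np.asarray(list(cue_onsets_ms), dtype=float)
    shifts = np.asarray(list(shift_frames), dtype=float)
    if len(shifts) != len(cues):
        raise ValueError("one shift per trial required")
    labels = np.zeros(len(t_ms), dtype=int)
    trial_ids = np.full(len(t_ms), -1, dtype=int)
    prev_end = -np.inf
    for i, (cue, s) in enumerate(zip(cues, shifts)):
        lo = cue + label_cfg.onset_s * 1000.0 + s * step_ms
        hi = cue + label_cfg.offset_s * 1000.0 + s * step_ms
        if lo <= prev_end:
            raise ValueError(f"grasp windows of trials {i - 1} and {i} overlap")
        prev_end = hi
        m = (t_ms >= lo - 1e-9) & (t_ms <= hi + 1e-9)
        labels[m] = 1
        trial_ids[m] = i
    return LabeledFrames(t_ms=t_ms, labels=labels, trial_ids=trial_ids)


@dataclass
class FoldAssignment:
    """k contiguous spans; rest downsampled per fold to match grasp counts."""

    fold_indices: list[np.ndarray]  # retained frame indices per fold, sorted
    spans: list[tuple[int, int]] = field(default_factory=list)  # [start, end) frame ranges
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.fold_indices)


def balance_and_fold(labeled: LabeledFrames, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Contiguous folds with equal grasp counts and per-fold rest downsampling.

    The timeline is cut into ``k`` contiguous spans each holding an equal
    (to within one) number of grasp frames; within each span, rest frames
    are randomly downsampled to the span's grasp count.  Grasp frames are
    never dropped.
    """
    labels = labeled.labels
    grasp_idx = np.nonzero(labels == 1)[0]
    g = len(grasp_idx)
    if g < k:
        raise ValueError(f"only {g} grasp frames for {k} folds")
    if (labels == 0).sum() == 0:
        raise ValueError("no rest frames present")
    quotas = [g // k + (1 if i < g % k else 0) for i in range(k)]
    rng = np.random.default_rng(seed)
    fold_indices: list[np.ndarray] = []
    spans: list[tuple[int, int]] = []
    start = 0
    taken = 0
    for fi, q in enumerate(quotas):
        # span runs through the last quota grasp, up to (not including) the
        # next fold's first grasp frame
        end = len(labels) if fi == k - 1 else int(grasp_idx[taken + q])
        span = np.arange(start, end)
        g_in = span[labels[span] == 1]
        r_in = span[labels[span] == 0]
        keep_rest = rng.choice(r_in, size=min(len(g_in), len(r_in)), replace=False)
        if len(keep_rest) < len(g_in):
            raise ValueError("a fold has fewer rest than grasp frames; cannot balance")
        fold_indices.append(np.sort(np.concatenate([g_in, keep_rest])))
        spans.append((start, end))
        start = end
        taken += q
    return FoldAssignment(fold_indices=fold_indices, spans=spans, seed=seed)
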