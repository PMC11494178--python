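"""Event-based detection and spelling performance metrics.

Sensitivity = N_correct_clicks / N_attempted_grasps x 100%; TPF and FPF
are true/false positive clicks per minute of session time.  A click is
correct when it appears on screen within 1.5 s (inclusive) after a grasp
onset; matching is greedy earliest-click-first with at most one click per
grasp.  Spelling rates (CCPM/WCPM/CWPM) use position-exact matching
against the prompt.  Uncertainty uses the bias-corrected and accelerated
(BCa) bootstrap with 10,000 replicates; group comparisons use the
two-sided Wilcoxon rank-sum with normal approximation (continuity and tie
corrected) and Holm step-down adjustment across a declared family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detector import ClickEvent


@dataclass
class EventAlignment:
    """TP/FP/FN partition of one session's grasps and clicks."""

    tp: list[tuple[float, ClickEvent]]  # (grasp_onset_ms, matched click)
    fn: list[float]  # unmatched grasp onsets
    fp: list[ClickEvent]  # unmatched clicks
    tp_window_ms: float
    duration_min: float

    @property
    def n_attempted(self) -> int:
        return len(self.tp) + len(self.fn)

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp)


def _as_click(c) -> ClickEvent:
    if isinstance(c, ClickEvent):
        return c
    return ClickEvent(detect_t_ms=float(c), onscreen_t_ms=float(c))


def align_events(
    grasp_onsets_ms, clicks, duration_min: float, tp_window_ms: float = 1500.0
) -> EventAlignment:
    """Greedy earliest-first matching of on-screen clicks to grasp onsets.

    A click matches the earliest unmatched grasp such that
    0 <= click_onscreen - onset <= tp_window_ms (boundary inclusive);
    unmatched clicks are false positives, unmatched grasps false negatives.
    """
    onsets = [float(g) for g in grasp_onsets_ms]
    events = [_as_click(c) for c in clicks]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("grasp onsets must be time-sorted")
    times = [c.onscreen_t_ms for c in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("clicks must be time-sorted")
    matched = [False] * len(onsets)
    tp, fp = [], []
    for c in events:
        hit = None
        for gi, g in enumerate(onsets):
            if matched[gi]:
                continue
            if 0.0 <= c.onscreen_t_ms - g <= tp_window_ms:
                hit = gi
                break
            if g > c.onscreen_t_ms:
                break
        if hit is None:
            fp.append(c)
        else:
            matched[hit] = True
            tp.append((onsets[hit], c))
    fn = [g for g, m in zip(onsets, matched) if not m]
    return EventAlignment(tp=tp, fn=fn, fp=fp, tp_window_ms=tp_window_ms, duration_min=duration_min)


def sensitivity(alignment: EventAlignment) -> float:
    """Percentage of attempted grasps that produced a correct click."""
    if alignment.n_attempted == 0:
        raise ValueError("sensitivity undefined with zero attempted grasps")
    return alignment.n_tp / alignment.n_attempted * 100.0


def rates(alignment: EventAlignment) -> tuple[float, float]:
    """(TPF, FPF) in clicks per minute."""
    if alignment.duration_min <= 0:
        raise ValueError("session duration must be positive")
    return (
        alignment.n_tp / alignment.duration_min,
        alignment.n_fp / alignment.duration_min,
    )


def per_hour(rate_per_min: float) -> float:
    return rate_per_min * 60.0


def _summary(x: np.ndarray) -> dict:
    return {
        "median": float(np.median(x)),
        "mean": float(np.mean(x)),
        "q1": float(np.percentile(x, 25)),
        "q3": float(np.percentile(x, 75)),
        "n": int(len(x)),
    }


def latency_stats(alignment: EventAlignment) -> dict:
    """Onset-to-detection and onset-to-on-screen latency summaries (ms)."""
    if alignment.n_tp == 0:
        raise ValueError("no true positives: latencies undefined")
    detect = np.array([c.detect_t_ms - g for g, c in alignment.tp])
    onscreen = np.array([c.onscreen_t_ms - g for g, c in alignment.tp])
    return {
        "detect_ms": _summary(detect),
        "onscreen_ms": _summary(onscreen),
        "onscreen_minus_detect_ms": _summary(onscreen - detect),
    }


@dataclass
class SpellingRates:
    ccpm: float
    wcpm: float
    cwpm: float
    n_correct_chars: int
    n_wrong_chars: int
    n_correct_words: int


def spelling_rates(prompt: str, typed: str, duration_min: float) -> SpellingRates:
    """Position-exact character/word matching against the prompt, per minute.

    Words are whitespace-delimited; a word counts only if it equals the
    prompt token at the same position.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    n_correct = sum(1 for a, b in zip(prompt, typed) if a == b)
    n_wrong = len(typed) - n_correct
    pw, tw = prompt.split(), typed.split()
    n_words = sum(1 for a, b in zip(pw, tw) if a == b)
    return SpellingRates(
        ccpm=n_correct / duration_min,
        wcpm=n_wrong / duration_min,
        cwpm=n_words / duration_min,
        n_correct_chars=n_correct,
        n_wrong_chars=n_wrong,
        n_correct_words=n_words,
    )


def bootstrap_ci(
    values,
    n_replicates: int = 10000,
    seed: int = 0,
    confidence_level: float = 0.95,
    statistic=np.mean,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the mean (or other statistic)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values to bootstrap")
    if np.ptp(values) == 0:
        warnings.warn("constant sample: degenerate confidence interval", stacklevel=2)
        return float(values[0]), float(values[0])
    res = stats.bootstrap(
        (values,),
        statistic,
        n_resamples=n_replicates,
        confidence_level=confidence_level,
        method="BCa",
        random_state=np.random.default_rng(seed),
    )
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: (z statistic, p).

    Normal approximation with tie correction and a 0.5 continuity
    correction toward the null.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie = ((counts**3 - counts).sum()) / ((n * (n - 1)) if n > 1 else 1.0)
    var = n1 * n2 / 12.0 * (n + 1 - tie)
    if var <= 0:
        return 0.0, 1.0
    d = w - mu
    cc = 0.5 * np.sign(d) if d != 0 else 0.0
    z = (d - cc) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def holm(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone, >= raw)."""
    from statsmodels.stats.multitest import multipletests

    _, adj, _, _ = multipletests(np.asarray(p_values, dtype=float), method="holm")
    return adj


def compare_groups(family: list[tuple]) -> list[dict]:
    """Rank-sum tests over a family of (a, b) pairs with Holm adjustment."""
    raw = [rank_sum(a, b) for a, b in family]
    adj = holm([p for _, p in raw])
    return [
        {"z": z, "p": p, "p_holm": float(ph)} for (z, p), ph in zip(raw, adj)
    ]
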