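"""Switch-scanning communication board and sentence speller simulator.

Rows of a key grid are sequentially highlighted at the scan rate; a click
selects the highlighted row, after which its columns are scanned and a
second click executes the highlighted key.  Cycles open with dummy
pre-selection steps (3 for rows, 1 for columns) that give the user
preparation time; clicks landing on a pre-selection step are ignored.
Typing a plain letter therefore costs exactly two clicks.

Autocomplete slots are filled by a pluggable suggestion engine; the
default is a deterministic word/letter-frequency n-gram model over a
small packaged corpus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .detector import ClickEvent, DetectorState, VotingConfig, vote_step
from .io import EVENT_COLUMNS
from .synth import SynthConfig, StreamingSynth, UserModelConfig, simulate_user

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Layout


@dataclass(frozen=True)
class Key:
    id: str
    kind: str  # letter | space | del | adel | enter | word | letter_sugg | symbol


@dataclass
class SpellerLayout:
    rows: list[list[Key]]
    mode: str = "speller"

    def __post_init__(self) -> None:
        if not self.rows or any(not r for r in self.rows):
            raise ValueError("layout rows must be non-empty")
        ids = [k.id for r in self.rows for k in r]
        if len(ids) != len(set(ids)):
            raise ValueError("key identifiers must be unique")
        if self.mode == "speller":
            kinds = {k.kind for r in self.rows for k in r}
            if not {"del", "adel", "enter"} <= kinds:
                raise ValueError("speller mode requires DEL, A-DEL and ENTER keys")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row_len(self, r: int) -> int:
        return len(self.rows[r])

    def locate(self, key_id: str) -> tuple[int, int] | None:
        """(row, column) of a key id; ' ' resolves to the SPACE key."""
        if key_id == " ":
            key_id = "SPACE"
        for r, row in enumerate(self.rows):
            for c, k in enumerate(row):
                if k.id == key_id:
                    return r, c
        return None

    def to_json(self) -> str:
        return json.dumps(
            {"mode": self.mode,
             "rows": [[[k.id, k.kind] for k in r] for r in self.rows]},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SpellerLayout":
        d = json.loads(text)
        rows = [[Key(i, kind) for i, kind in r] for r in d["rows"]]
        return cls(rows=rows, mode=d.get("mode", "speller"))


def default_layout(n_word_slots: int = 3, n_letter_slots: int = 3) -> SpellerLayout:
    """Alphabet grid with suggestion rows, SPACE, DEL, A-DEL and ENTER."""
    rows = [
        [Key(f"W{i + 1}", "word") for i in range(n_word_slots)],
        [Key(f"L{i + 1}", "letter_sugg") for i in range(n_letter_slots)],
        [Key(c, "letter") for c in "abcdefg"],
        [Key(c, "letter") for c in "hijklmn"],
        [Key(c, "letter") for c in "opqrstu"],
        [Key(c, "letter") for c in "vwxyz"] + [Key("SPACE", "space")],
        [Key("DEL", "del"), Key("A-DEL", "adel"), Key("ENTER", "enter")],
    ]
    return SpellerLayout(rows=rows)


def board_layout() -> SpellerLayout:
    """Medical communication board: symbol grid, no text editing keys."""
    symbols = [
        ["yes", "no", "pain", "water"],
        ["food", "rest", "hot", "cold"],
        ["nurse", "doctor", "family", "thanks"],
    ]
    rows = [[Key(s, "symbol") for s in r] for r in symbols]
    return SpellerLayout(rows=rows, mode="board")


# ---------------------------------------------------------------------------
# Suggestion engines


class NGramEngine:
    """Deterministic frequency-ordered word and next-letter completion."""

    def __init__(self, corpus: dict[str, int] | None = None):
        if corpus is None:
            text = resources.files("bciclick").joinpath("data/wordlist.txt").read_text()
            corpus = {}
            for line in text.strip().splitlines():
                w, c = line.split()
                corpus[w] = corpus.get(w, 0) + int(c)
        self.corpus = corpus

    def suggest_words(self, prefix: str, k: int) -> list[str]:
        cand = [(w, c) for w, c in self.corpus.items() if w.startswith(prefix)]
        cand.sort(key=lambda wc: (-wc[1], wc[0]))
        return [w for w, _ in cand[:k]]

    def suggest_letters(self, prefix: str, k: int) -> list[str]:
        freq: dict[str, int] = {}
        for w, c in self.corpus.items():
            if w.startswith(prefix) and len(w) > len(prefix):
                nxt = w[len(prefix)]
                freq[nxt] = freq.get(nxt, 0) + c
        out = sorted(freq.items(), key=lambda lc: (-lc[1], lc[0]))
        return [l for l, _ in out[:k]]


def suggest(typed: str, engine, n_word_slots: int, n_letter_slots: int):
    """(word completions, next-letter completions) for the current partial word.

    Engine failures degrade to empty suggestions and are logged.
    """
    partial = typed.rsplit(" ", 1)[-1]
    try:
        words = list(engine.suggest_words(partial, n_word_slots))[:n_word_slots]
        letters = list(engine.suggest_letters(partial, n_letter_slots))[:n_letter_slots]
        return words, letters
    except Exception:
        logger.exception("suggestion engine failed; returning empty suggestions")
        return [], []


# ---------------------------------------------------------------------------
# Scan state machine


@dataclass
class ScanConfig:
    scan_rate_hz: float = 0.67
    preselect_rows: int = 3
    preselect_cols: int = 1
    mode: str = "speller"  # or "board"

    def __post_init__(self) -> None:
        if self.scan_rate_hz <= 0:
            raise ValueError("scan rate must be positive")

    @property
    def step_period_ms(self) -> float:
        return 1000.0 / self.scan_rate_hz


@dataclass
class SpellerState:
    layout: SpellerLayout
    prompt: str = ""
    phase: str = "row"  # row-scan or column-scan
    pos: int = 0  # negative during pre-selection steps
    selected_row: int | None = None
    typed: str = ""
    pending_error: bool = False
    last_output_len: int = 1
    finalized: list[str] = field(default_factory=list)
    word_slots: list[str] = field(default_factory=list)
    letter_slots: list[str] = field(default_factory=list)

    @property
    def highlight(self) -> int | None:
        return self.pos if self.pos >= 0 else None


def fresh_state(layout: SpellerLayout, cfg: ScanConfig, prompt: str = "") -> SpellerState:
    return SpellerState(layout=layout, prompt=prompt, phase="row", pos=-cfg.preselect_rows)


def _restart_cycle(state: SpellerState, cfg: ScanConfig) -> None:
    state.phase = "row"
    state.pos = -cfg.preselect_rows
    state.selected_row = None


def advance(state: SpellerState, cfg: ScanConfig) -> SpellerState:
    """One scan step: consume a pre-selection step or move the highlight,
    wrapping cyclically (pre-selection steps recur at each cycle start)."""
    limit = (
        state.layout.n_rows
        if state.phase == "row"
        else state.layout.row_len(state.selected_row)
    )
    pre = cfg.preselect_rows if state.phase == "row" else cfg.preselect_cols
    state.pos += 1
    if state.pos >= limit:
        state.pos = -pre
    return state


def apply_click(
    state: SpellerState, cfg: ScanConfig, engine=None
) -> tuple[SpellerState, dict]:
    """Consume one click: select the row, or execute the highlighted key."""
    if state.highlight is None:
        return state, {"action": "ignored-preselect"}
    if state.phase == "row":
        state.selected_row = state.pos
        state.phase = "col"
        state.pos = -cfg.preselect_cols
        return state, {"action": "row-select", "row": state.selected_row}
    key = state.layout.rows[state.selected_row][state.pos]
    action: dict = {"action": "key", "key": key.id, "kind": key.kind}
    if key.kind == "letter":
        state.typed += key.id
        state.last_output_len = 1
    elif key.kind == "space":
        state.typed += " "
        state.last_output_len = 1
    elif key.kind == "letter_sugg":
        slot = int(key.id[1:]) - 1
        ch = state.letter_slots[slot] if slot < len(state.letter_slots) else ""
        state.typed += ch
        state.last_output_len = max(len(ch), 1)
        action["content"] = ch
    elif key.kind == "word":
        slot = int(key.id[1:]) - 1
        word = state.word_slots[slot] if slot < len(state.word_slots) else ""
        partial = state.typed.rsplit(" ", 1)[-1]
        insertion = (word[len(partial):] + " ") if word.startswith(partial) else ""
        state.typed += insertion
        state.last_output_len = max(len(insertion), 1)
        action["content"] = word
    elif key.kind == "del":
        state.typed = state.typed[:-1]
        state.last_output_len = 1
    elif key.kind == "adel":
        n = max(state.last_output_len, 1)
        state.typed = state.typed[:-n]
        state.last_output_len = 1
    elif key.kind == "enter":
        state.finalized.append(state.typed)
        action["sentence"] = state.typed
        state.typed = ""
        state.last_output_len = 1
    state.pending_error = bool(state.prompt) and not state.prompt.startswith(state.typed)
    if engine is not None and state.layout.mode == "speller":
        n_w = sum(k.kind == "word" for r in state.layout.rows for k in r)
        n_l = sum(k.kind == "letter_sugg" for r in state.layout.rows for k in r)
        state.word_slots, state.letter_slots = suggest(state.typed, engine, n_w, n_l)
    _restart_cycle(state, cfg)
    return state, action


# ---------------------------------------------------------------------------
# Detectors for the closed loop


class OracleDetector:
    """Emits a click a fixed latency after each notified grasp intent.

    ``miss_prob`` drops intents at random to emulate an imperfect
    (sensitivity < 1) detector.
    """

    def __init__(
        self,
        detect_latency_ms: float = 400.0,
        onscreen_delay_ms: float = 200.0,
        miss_prob: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        self.detect_latency_ms = detect_latency_ms
        self.onscreen_delay_ms = onscreen_delay_ms
        self.miss_prob = miss_prob
        self.rng = rng or np.random.default_rng(0)
        self._pending: list[float] = []

    def notify_intent(self, t_ms: float) -> None:
        if self.miss_prob > 0 and self.rng.uniform() < self.miss_prob:
            return
        self._pending.append(t_ms + self.detect_latency_ms)

    def step(self, t_ms: float, frame_ms: float) -> list[ClickEvent]:
        due = [d for d in self._pending if d < t_ms + frame_ms]
        self._pending = [d for d in self._pending if d >= t_ms + frame_ms]
        return [
            ClickEvent(detect_t_ms=d, onscreen_t_ms=d + self.onscreen_delay_ms)
            for d in due
        ]


class ModelStreamDetector:
    """Full signal path: synthetic stream -> features -> LSTM -> voting."""

    def __init__(
        self,
        synth_cfg: SynthConfig,
        model,
        calib,
        spectral_cfg,
        voting_cfg: VotingConfig,
        seed: int = 0,
    ):
        from .spectral import StreamingExtractor  # deferred: keeps module deps one-way

        self.synth = StreamingSynth(synth_cfg, seed=seed)
        self.model = model
        self.extractor = StreamingExtractor(calib, spectral_cfg)
        self.voting_cfg = voting_cfg
        self.vote_state = DetectorState()
        self._history: list[np.ndarray] = []
        self._frame_samples = int(round(spectral_cfg.fs_hz * 0.1))

    def notify_intent(self, t_ms: float) -> None:
        self.synth.add_grasp(t_ms)

    def step(self, t_ms: float, frame_ms: float) -> list[ClickEvent]:
        chunk = self.synth.next_chunk(int(round(frame_ms / 1000.0 * self.synth.cfg.fs_hz)))
        clicks = []
        for frame in self.extractor.push(chunk):
            self._history.append(frame.hg)
            L = self.model.cfg.seq_len
            if len(self._history) < L:
                label = 0  # warm-up convention: rest until the buffer fills
            else:
                seq = np.stack(self._history[-L:])
                label = int(self.model.predict_proba(seq[None]).argmax())
            ev = vote_step(self.vote_state, label, frame.t_ms, self.voting_cfg)
            if ev is not None:
                clicks.append(ev)
        return clicks


# ---------------------------------------------------------------------------
# Closed loop


@dataclass
class SessionLog:
    events: pd.DataFrame  # time_ms, event_type, detail
    typed_sentences: list[str]
    prompts: list[str]
    grasp_onsets_ms: list[float]
    clicks: list[ClickEvent]
    duration_ms: float

    @property
    def duration_min(self) -> float:
        return self.duration_ms / 60000.0


def run_closed_loop(
    prompts: list[str],
    detector,
    user_cfg: UserModelConfig | None = None,
    scan_cfg: ScanConfig | None = None,
    layout: SpellerLayout | None = None,
    engine=None,
    seed: int = 0,
    frame_ms: float = 100.0,
    max_duration_s: float = 3600.0,
) -> SessionLog:
    """Simulate prompted spelling: scan steps, user intents, clicks, typing.

    The loop ticks at the 100 ms classification cadence; the speller
    advances every scan period, the user model schedules grasp intents when
    the highlight matches the next needed key, the detector turns intents
    into clicks, and on-screen clicks drive the state machine.
    """
    user_cfg = user_cfg or UserModelConfig()
    scan_cfg = scan_cfg or ScanConfig()
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    state = fresh_state(layout, scan_cfg, prompts[0])
    if engine is not None:
        n_w = sum(k.kind == "word" for r in layout.rows for k in r)
        n_l = sum(k.kind == "letter_sugg" for r in layout.rows for k in r)
        state.word_slots, state.letter_slots = suggest("", engine, n_w, n_l)
    period_frames = max(1, int(round(scan_cfg.step_period_ms / frame_ms)))
    events: list[tuple] = []
    grasp_onsets: list[float] = []
    clicks: list[ClickEvent] = []
    pending_intents: list[float] = []
    pending_ui: list[ClickEvent] = []
    prompt_i = 0
    t = 0.0
    n_frames = int(max_duration_s * 1000.0 / frame_ms)
    for fi in range(n_frames):
        t = fi * frame_ms
        if fi > 0 and fi % period_frames == 0:
            advance(state, scan_cfg)
            events.append((t, "scan-step", f"{state.phase}:{state.pos}"))
        if fi % period_frames == 0:
            intend, offset = simulate_user(state, state.prompt, user_cfg, rng)
            if intend:
                pending_intents.append(t + offset)
        for it in [x for x in pending_intents if x < t + frame_ms]:
            pending_intents.remove(it)
            grasp_onsets.append(it)
            events.append((it, "grasp-onset", ""))
            detector.notify_intent(it)
        for ev in detector.step(t, frame_ms):
            clicks.append(ev)
            events.append((ev.detect_t_ms, "click-detect", ""))
            pending_ui.append(ev)
        for ev in [x for x in pending_ui if x.onscreen_t_ms < t + frame_ms]:
            pending_ui.remove(ev)
            events.append((ev.onscreen_t_ms, "click-onscreen", ""))
            state, action = apply_click(state, scan_cfg, engine)
            events.append((ev.onscreen_t_ms, "selection", json.dumps(action)))
            if action.get("kind") == "enter":
                events.append((ev.onscreen_t_ms, "sentence-final", action["sentence"]))
                prompt_i += 1
                if prompt_i >= len(prompts):
                    df = pd.DataFrame(events, columns=EVENT_COLUMNS)
                    return SessionLog(
                        events=df,
                        typed_sentences=list(state.finalized),
                        prompts=prompts,
                        grasp_onsets_ms=grasp_onsets,
                        clicks=clicks,
                        duration_ms=t + frame_ms,
                    )
                state.prompt = prompts[prompt_i]
    df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return SessionLog(
        events=df,
        typed_sentences=list(state.finalized),
        prompts=prompts,
        grasp_onsets_ms=grasp_onsets,
        clicks=clicks,
        duration_ms=t + frame_ms,
    )
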