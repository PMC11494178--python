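"""Switch-scanning state machine, suggestion engine, and closed-loop spelling."""

import numpy as np
import pytest

import bciclick as bc
from bciclick.speller import ScanConfig, advance, apply_click, default_layout, fresh_state


@pytest.fixture()
def scan_cfg():
    return ScanConfig()


@pytest.fixture()
def state(scan_cfg):
    return fresh_state(default_layout(), scan_cfg, prompt="the")


class TestScanMachine:
    def test_first_row_highlights_on_step_four(self, state, scan_cfg):
        """Three pre-selection steps open every row-scan cycle."""
        assert state.highlight is None
        for _ in range(2):
            advance(state, scan_cfg)
            assert state.highlight is None
        advance(state, scan_cfg)
        assert state.highlight == 0

    def test_first_column_highlights_on_step_two(self, state, scan_cfg):
        for _ in range(3):
            advance(state, scan_cfg)
        apply_click(state, scan_cfg)  # selects row 0
        assert state.phase == "col"
        assert state.highlight is None  # one pre-selection column
        advance(state, scan_cfg)
        assert state.highlight == 0

    def test_row_scan_cyclic(self, state, scan_cfg):
        n = state.layout.n_rows + scan_cfg.preselect_rows
        before = state.pos
        for _ in range(n):
            advance(state, scan_cfg)
        assert state.pos == before

    def test_click_on_preselect_ignored(self, state, scan_cfg):
        _, action = apply_click(state, scan_cfg)
        assert action["action"] == "ignored-preselect"
        assert state.phase == "row"

    def test_two_clicks_type_one_letter(self, scan_cfg):
        layout = default_layout()
        st = fresh_state(layout, scan_cfg, prompt="a")
        r, c = layout.locate("a")
        for _ in range(scan_cfg.preselect_rows + r):
            advance(st, scan_cfg)
        _, a1 = apply_click(st, scan_cfg)
        assert a1 == {"action": "row-select", "row": r}
        for _ in range(scan_cfg.preselect_cols + c):
            advance(st, scan_cfg)
        _, a2 = apply_click(st, scan_cfg)
        assert a2["key"] == "a"
        assert st.typed == "a"
        assert st.phase == "row"  # cycle restarts after a key

    def test_wrong_letter_sets_pending_error_and_del_clears(self, scan_cfg):
        layout = default_layout()
        st = fresh_state(layout, scan_cfg, prompt="ab")
        st.typed = "ax"
        st.pending_error = True
        # navigate to DEL and click it
        r, c = layout.locate("DEL")
        st.phase, st.selected_row, st.pos = "col", r, c
        _, action = apply_click(st, scan_cfg)
        assert action["kind"] == "del"
        assert st.typed == "a"
        assert not st.pending_error

    def test_enter_finalizes_sentence(self, scan_cfg):
        layout = default_layout()
        st = fresh_state(layout, scan_cfg, prompt="hi")
        st.typed = "hi"
        r, c = layout.locate("ENTER")
        st.phase, st.selected_row, st.pos = "col", r, c
        _, action = apply_click(st, scan_cfg)
        assert action["sentence"] == "hi"
        assert st.finalized == ["hi"]
        assert st.typed == ""


class TestLayout:
    def test_layout_roundtrip_json(self):
        layout = default_layout()
        back = bc.SpellerLayout.from_json(layout.to_json())
        assert [[k.id for k in r] for r in back.rows] == [[k.id for k in r] for r in layout.rows]

    def test_speller_mode_requires_editing_keys(self):
        from bciclick.speller import Key

        with pytest.raises(ValueError):
            bc.SpellerLayout(rows=[[Key("a", "letter")]], mode="speller")

    def test_board_layout_is_board_mode(self):
        assert bc.board_layout().mode == "board"

    def test_duplicate_ids_rejected(self):
        from bciclick.speller import Key

        with pytest.raises(ValueError):
            bc.SpellerLayout(rows=[[Key("a", "letter"), Key("a", "letter")]], mode="board")


class TestSuggestions:
    def test_deterministic_frequency_order(self):
        engine = bc.NGramEngine()
        w1, l1 = bc.suggest("th", engine, 3, 3)
        w2, l2 = bc.suggest("th", engine, 3, 3)
        assert w1 == w2 and l1 == l2
        assert all(w.startswith("th") for w in w1)
        assert w1[0] == "the"  # highest-frequency completion first

    def test_empty_context_most_frequent(self):
        engine = bc.NGramEngine()
        words, letters = bc.suggest("", engine, 3, 3)
        assert words[0] == "the"
        assert len(words) == 3 and len(letters) == 3

    def test_oversized_engine_output_truncated(self):
        class Big:
            def suggest_words(self, p, k):
                return ["w%d" % i for i in range(50)]

            def suggest_letters(self, p, k):
                return list("abcdefghij")

        words, letters = bc.suggest("", Big(), 3, 2)
        assert len(words) == 3 and len(letters) == 2

    def test_failing_engine_degrades_to_empty(self):
        class Broken:
            def suggest_words(self, p, k):
                raise RuntimeError("down")

            def suggest_letters(self, p, k):
                raise RuntimeError("down")

        assert bc.suggest("x", Broken(), 3, 3) == ([], [])


class TestClosedLoop:
    def test_oracle_detector_types_prompt_exactly(self):
        prompt = "the birch canoe"
        log = bc.run_closed_loop([prompt], bc.OracleDetector(), seed=3, max_duration_s=3000)
        assert log.typed_sentences == [prompt]
        # click economy: 2 clicks per key press (letters, spaces, final ENTER)
        assert len(log.clicks) == 2 * (len(prompt) + 1)

    def test_same_seed_identical_log(self):
        a = bc.run_closed_loop(["hot"], bc.OracleDetector(), seed=9, max_duration_s=2000)
        b = bc.run_closed_loop(["hot"], bc.OracleDetector(), seed=9, max_duration_s=2000)
        assert a.events.equals(b.events)
        assert a.grasp_onsets_ms == b.grasp_onsets_ms

    def test_user_errors_trigger_delete_keys(self):
        """An imperfect user occasionally selects a wrong key, then recovers
        through DEL/A-DEL and still completes the prompt."""
        log = bc.run_closed_loop(
            ["water hot"],
            bc.OracleDetector(),
            user_cfg=bc.UserModelConfig(error_rate=0.1),
            seed=7,
            max_duration_s=3000,
        )
        sel = log.events[log.events.event_type == "selection"]
        n_del = sel.detail.str.contains('"del"').sum() + sel.detail.str.contains('"adel"').sum()
        assert n_del >= 1
        assert log.typed_sentences == ["water hot"]

    def test_liveness_with_missy_detector(self):
        """A detector that misses 30% of grasps still lets the session finish:
        the user re-attempts on the next cycle."""
        det = bc.OracleDetector(miss_prob=0.3, rng=np.random.default_rng(7))
        log = bc.run_closed_loop(["hi"], det, seed=7, max_duration_s=3000)
        assert log.typed_sentences == ["hi"]
        assert len(log.grasp_onsets_ms) > len(log.clicks)  # some attempts missed

    def test_intents_fall_within_highlight_period(self):
        log = bc.run_closed_loop(["tea"], bc.OracleDetector(), seed=4, max_duration_s=2000)
        # the loop quantizes the 0.67/s scan period to the 100 ms frame grid
        period = round(ScanConfig().step_period_ms / 100.0) * 100.0
        lo, hi = bc.UserModelConfig().reaction_latency_bounds_ms
        for g in log.grasp_onsets_ms:
            assert lo <= g % period <= hi

    def test_multi_prompt_session(self):
        prompts = ["hi", "go"]
        log = bc.run_closed_loop(prompts, bc.OracleDetector(), seed=6, max_duration_s=4000)
        assert log.typed_sentences == prompts
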