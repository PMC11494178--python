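"""Event alignment, detection/spelling rates, bootstrap CIs, rank-sum tests."""

import numpy as np
import pytest
from scipy import stats

import bciclick as bc
from bciclick.detector import ClickEvent


def click(t, delay=0.0):
    return ClickEvent(detect_t_ms=t - delay, onscreen_t_ms=t)


class TestAlignment:
    def test_click_inside_window_is_tp(self):
        al = bc.align_events([1000.0], [click(2400.0)], duration_min=1.0)
        assert al.n_tp == 1 and al.n_fp == 0 and not al.fn

    def test_boundary_click_at_exactly_1500ms_is_tp(self):
        al = bc.align_events([1000.0], [click(2500.0)], duration_min=1.0)
        assert al.n_tp == 1

    def test_click_outside_window_is_fp_and_fn(self):
        al = bc.align_events([1000.0], [click(2600.0)], duration_min=1.0)
        assert al.n_tp == 0 and al.n_fp == 1 and al.fn == [1000.0]

    def test_click_before_onset_never_matches(self):
        al = bc.align_events([1000.0], [click(900.0)], duration_min=1.0)
        assert al.n_fp == 1

    def test_zero_grasps_all_clicks_fp(self):
        al = bc.align_events([], [click(100.0), click(2000.0), click(4000.0)], duration_min=1.0)
        assert al.n_fp == 3

    def test_one_click_per_grasp(self):
        al = bc.align_events([1000.0], [click(1200.0), click(1400.0)], duration_min=1.0)
        assert al.n_tp == 1 and al.n_fp == 1

    def test_conservation(self):
        rng = np.random.default_rng(0)
        onsets = np.sort(rng.uniform(0, 60000, 20))
        clicks = [click(t) for t in np.sort(rng.uniform(0, 60000, 25))]
        al = bc.align_events(onsets, clicks, duration_min=1.0)
        assert al.n_tp + len(al.fn) == len(onsets)
        assert al.n_tp + al.n_fp == len(clicks)

    def test_unsorted_inputs_rejected(self):
        with pytest.raises(ValueError):
            bc.align_events([2000.0, 1000.0], [], duration_min=1.0)


class TestRates:
    def test_sensitivity_arithmetic(self):
        onsets = [1000.0 * i * 4 for i in range(1, 11)]
        clicks = [click(o + 500.0) for o in onsets[:9]]
        al = bc.align_events(onsets, clicks, duration_min=1.0)
        assert bc.sensitivity(al) == 90.0

    def test_sensitivity_bounds(self):
        al = bc.align_events([1000.0], [click(1400.0)], duration_min=1.0)
        assert bc.sensitivity(al) == 100.0
        al0 = bc.align_events([1000.0], [], duration_min=1.0)
        assert bc.sensitivity(al0) == 0.0
        with pytest.raises(ValueError):
            bc.sensitivity(bc.align_events([], [], duration_min=1.0))

    def test_fpf_arithmetic_and_per_hour(self):
        al = bc.align_events([], [click(100.0), click(2000.0)], duration_min=10.0)
        tpf, fpf = bc.rates(al)
        assert tpf == 0.0 and fpf == pytest.approx(0.2)
        assert bc.metrics.per_hour(0.029) == pytest.approx(1.74)

    def test_zero_duration_rejected(self):
        al = bc.align_events([], [], duration_min=0.0)
        with pytest.raises(ValueError):
            bc.rates(al)

    def test_counting_oracle_on_constructed_session(self):
        """Sensitivity/TPF/FPF equal a brute-force counting oracle."""
        rng = np.random.default_rng(1)
        onsets = np.sort(rng.uniform(0, 300000, 40))
        onsets = onsets[np.insert(np.diff(onsets) > 3000, 0, True)]
        clicks = []
        for o in onsets:  # 70% clicked, some spurious
            if rng.uniform() < 0.7:
                clicks.append(o + rng.uniform(0, 1500))
            if rng.uniform() < 0.2:
                clicks.append(o + rng.uniform(1800, 2800))
        clicks = [click(t) for t in sorted(clicks)]
        T = 5.0
        al = bc.align_events(onsets, clicks, duration_min=T)
        # oracle: count each grasp with >= 1 click in window; rest are FPs
        n_tp = 0
        used = set()
        for o in onsets:
            for i, c in enumerate(clicks):
                if i not in used and 0 <= c.onscreen_t_ms - o <= 1500:
                    n_tp += 1
                    used.add(i)
                    break
        assert al.n_tp == n_tp
        assert al.n_fp == len(clicks) - n_tp
        assert bc.sensitivity(al) == pytest.approx(100.0 * n_tp / len(onsets))
        tpf, fpf = bc.rates(al)
        assert tpf == pytest.approx(n_tp / T) and fpf == pytest.approx((len(clicks) - n_tp) / T)


class TestLatencies:
    def test_constant_onscreen_offset(self):
        onsets = [0.0, 5000.0]
        clicks = [click(o + 600.0, delay=200.0) for o in onsets]
        al = bc.align_events(onsets, clicks, duration_min=1.0)
        s = bc.latency_stats(al)
        assert s["onscreen_minus_detect_ms"]["mean"] == 200.0
        assert s["detect_ms"]["median"] == 400.0

    def test_single_tp_median_equals_mean(self):
        al = bc.align_events([0.0], [click(700.0)], duration_min=1.0)
        s = bc.latency_stats(al)
        assert s["onscreen_ms"]["median"] == s["onscreen_ms"]["mean"] == 700.0

    def test_no_tp_rejected(self):
        al = bc.align_events([0.0], [], duration_min=1.0)
        with pytest.raises(ValueError):
            bc.latency_stats(al)


class TestSpellingRates:
    def test_single_typo_drops_char_and_word(self):
        """30 characters / 5 words with one typo: 29 chars and 4 words count."""
        prompt = "alpha bravo charlie delta echo"
        typed = "alpha bravo charlie delta echX"
        assert len(prompt) == 30 and len(prompt.split()) == 5
        sr = bc.spelling_rates(prompt, typed, 1.0)
        assert sr.n_correct_chars == 29
        assert sr.n_correct_words == 4
        assert sr.n_wrong_chars == 1

    def test_perfect_transcription_rates(self):
        sr = bc.spelling_rates("aaaaa aaaaa aaaaa aaa", "aaaaa aaaaa aaaaa aaa", 2.0)
        assert sr.ccpm == pytest.approx(21 / 2.0)
        assert sr.wcpm == 0.0

    def test_empty_output(self):
        sr = bc.spelling_rates("abc", "", 1.0)
        assert sr.ccpm == 0.0 and sr.cwpm == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            bc.spelling_rates("a", "a", 0.0)


class TestBootstrap:
    def test_constant_sample_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            lo, hi = bc.bootstrap_ci([3.0, 3.0, 3.0], seed=0)
        assert lo == hi == 3.0

    def test_same_seed_same_interval(self):
        x = np.random.default_rng(2).normal(size=20)
        assert bc.bootstrap_ci(x, seed=5) == bc.bootstrap_ci(x, seed=5)

    def test_interval_brackets_sample_mean(self):
        x = np.random.default_rng(3).normal(loc=2.0, size=40)
        lo, hi = bc.bootstrap_ci(x, seed=1)
        assert lo < x.mean() < hi

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bc.bootstrap_ci([1.0])


class TestGroupComparison:
    def test_identical_groups_p_near_one(self):
        x = np.arange(10.0)
        z, p = bc.rank_sum(x, x)
        assert p >= 0.9

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, 9)
        b = rng.normal(3.0, 1.0, 9)  # 3 SD shift
        _, p = bc.rank_sum(a, b)
        assert p < 0.01

    def test_z_sign_tracks_direction(self):
        a, b = np.arange(9.0), np.arange(9.0) + 100.0
        z_ab, _ = bc.rank_sum(a, b)
        z_ba, _ = bc.rank_sum(b, a)
        assert z_ab < 0 < z_ba

    def test_agrees_with_scipy_mannwhitney(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        _, p = bc.rank_sum(a, b)
        p_ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_holm_monotone_and_geq_raw(self):
        ps = [0.001, 0.04, 0.03, 0.5]
        adj = bc.holm(ps)
        assert np.all(adj >= np.asarray(ps))
        fam = [(np.arange(9.0), np.arange(9.0) + d) for d in (0.0, 5.0, 0.1)]
        out = bc.compare_groups(fam)
        for r in out:
            assert r["p_holm"] >= r["p"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bc.rank_sum([], [1.0])
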