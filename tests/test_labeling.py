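"""Channel selection, shift-warp recovery, label windows, balanced folds."""

import numpy as np
import pytest

import bciclick as bc
from bciclick.labeling import mean_pairwise_correlation


def bump(n_frames, center, width, amp=1.0):
    t = np.arange(n_frames)
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def make_tensor(shifts, n_frames=36, channels=(5, 9), n_channels=12, noise=0.05, seed=0):
    """Trials x frames x channels with a bump planted on given channels,
    displaced per trial by the given frame shifts."""
    rng = np.random.default_rng(seed)
    tensor = noise * rng.normal(size=(len(shifts), n_frames, n_channels))
    for i, s in enumerate(shifts):
        for c in channels:
            tensor[i, :, c] += bump(n_frames, 15 + s, 3.0, amp=3.0)
    return tensor


class TestChannelSelection:
    def test_planted_channels_recovered(self):
        tensor = make_tensor([0] * 8, channels=(5, 9))
        sel = bc.select_modulated_channels(tensor, 2)
        assert set(sel) == {5, 9}

    def test_tie_breaks_to_lowest_index(self):
        tensor = np.ones((6, 20, 4))
        sel = bc.select_modulated_channels(tensor, 2)
        np.testing.assert_array_equal(sel, [0, 1])

    def test_deterministic_on_noise(self):
        rng = np.random.default_rng(3)
        tensor = rng.normal(size=(6, 20, 8))
        a = bc.select_modulated_channels(tensor, 3)
        b = bc.select_modulated_channels(tensor, 3)
        np.testing.assert_array_equal(a, b)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            bc.select_modulated_channels(np.zeros((3, 20, 4)), 2)
        with pytest.raises(ValueError):
            bc.select_modulated_channels(np.zeros((6, 20, 4)), 9)


class TestShiftWarp:
    def test_identical_trials_zero_shifts(self):
        tensor = np.tile(make_tensor([0])[0], (5, 1, 1))
        res = bc.fit_shift_warp(tensor)
        np.testing.assert_array_equal(res.shift_frames, 0)
        assert res.converged

    def test_planted_shifts_recovered_up_to_constant(self):
        """Fit on the modulated-channel subset, as the pipeline does."""
        planted = [0, 2, -1]
        tensor = make_tensor(planted, noise=0.02)
        res = bc.fit_shift_warp(tensor, channels_used=np.array([5, 9]))
        rec = res.shift_frames - res.shift_frames[0]
        np.testing.assert_array_equal(rec, np.array(planted) - planted[0])

    def test_alignment_increases_intertrial_correlation(self):
        planted = [0, 3, -2, 1, -1, 2]
        tensor = make_tensor(planted, noise=0.3, seed=4)
        res = bc.fit_shift_warp(tensor)
        before = mean_pairwise_correlation(tensor)
        after = mean_pairwise_correlation(tensor, -res.shift_frames * 0 + res.shift_frames)
        assert after >= before

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            bc.fit_shift_warp(make_tensor([0])[:1])


class TestOnsetOffset:
    rel_t = np.arange(-10, 26) * 100.0  # -1.0 .. 2.5 s

    def test_boxcar_recovered(self):
        trace = np.where((self.rel_t >= 250) & (self.rel_t <= 1050), 1.0, 0.0)
        on, off = bc.estimate_onset_offset(trace, self.rel_t, 0.5)
        assert on == pytest.approx(0.3, abs=0.1)
        assert off == pytest.approx(1.0, abs=0.1)

    def test_override_returned_verbatim(self):
        trace = np.zeros_like(self.rel_t)
        assert bc.estimate_onset_offset(trace, self.rel_t, override=(0.3, 1.1)) == (0.3, 1.1)

    def test_flat_trace_errors(self):
        with pytest.raises(ValueError):
            bc.estimate_onset_offset(np.zeros_like(self.rel_t), self.rel_t)


class TestAssignLabels:
    def test_nine_frames_in_closed_800ms_window(self):
        t = np.arange(0, 10000, 100.0)
        lab = bc.assign_labels(t, [5000.0], [0], bc.LabelConfig())
        grasp_t = t[lab.labels == 1]
        np.testing.assert_array_equal(grasp_t, np.arange(5300, 6101, 100.0))
        assert lab.labels.sum() == 9
        assert set(lab.trial_ids[lab.labels == 1]) == {0}

    def test_shift_translates_window_by_200ms(self):
        t = np.arange(0, 10000, 100.0)
        lab = bc.assign_labels(t, [5000.0], [2], bc.LabelConfig())
        grasp_t = t[lab.labels == 1]
        np.testing.assert_array_equal(grasp_t, np.arange(5500, 6301, 100.0))

    def test_window_length_is_offset_minus_onset(self):
        cfg = bc.LabelConfig()
        assert cfg.offset_s - cfg.onset_s == pytest.approx(0.8)

    def test_overlapping_windows_rejected(self):
        t = np.arange(0, 10000, 100.0)
        with pytest.raises(ValueError):
            bc.assign_labels(t, [5000.0, 5400.0], [0, 0], bc.LabelConfig())

    def test_label_config_invariants(self):
        with pytest.raises(ValueError):
            bc.LabelConfig(onset_s=1.2, offset_s=1.1)
        with pytest.raises(ValueError):
            bc.LabelConfig(onset_s=0.3, offset_s=3.0)


@pytest.fixture(scope="module")
def folded():
    t = np.arange(0, 120000, 100.0)
    cues = np.arange(2000, 110000, 3500.0)
    lab = bc.assign_labels(t, cues, np.zeros(len(cues)), bc.LabelConfig())
    return lab, bc.balance_and_fold(lab, k=10, seed=3)


class TestFolds:
    def test_each_fold_balanced(self, folded):
        lab, folds = folded
        for idx in folds.fold_indices:
            assert (lab.labels[idx] == 1).sum() == (lab.labels[idx] == 0).sum()

    def test_partition_no_overlap(self, folded):
        _, folds = folded
        all_idx = np.concatenate(folds.fold_indices)
        assert len(all_idx) == len(np.unique(all_idx))

    def test_folds_contiguous_spans(self, folded):
        _, folds = folded
        for (s, e), idx in zip(folds.spans, folds.fold_indices):
            assert s <= idx.min() and idx.max() < e
        starts = [s for s, _ in folds.spans]
        assert starts == sorted(starts)

    def test_downsampling_never_drops_grasp(self, folded):
        lab, folds = folded
        kept = np.concatenate(folds.fold_indices)
        n_grasp_kept = (lab.labels[kept] == 1).sum()
        assert n_grasp_kept == (lab.labels == 1).sum()

    def test_too_few_grasps_rejected(self):
        t = np.arange(0, 10000, 100.0)
        lab = bc.assign_labels(t, [5000.0], [0], bc.LabelConfig())
        with pytest.raises(ValueError):
            bc.balance_and_fold(lab, k=10)


class TestEndToEndRecovery:
    def test_planted_reaction_delays_recovered(self, labeled_session):
        """Shift warping on real synthetic features recovers the per-trial
        reaction delays to within one frame, up to a global constant."""
        d = labeled_session
        delays = np.asarray(d["gt"].per_trial_delay_ms)
        planted = delays / 100.0
        rec = d["warp"].shift_frames.astype(float)
        resid = (rec - rec.mean()) - (planted - planted.mean())
        assert np.abs(resid).max() <= 1.0

    def test_selected_channels_are_hand_channels(self, labeled_session, synth_cfg):
        assert set(labeled_session["channels"]) <= set(synth_cfg.hand_channels)
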