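"""Shared fixtures: one small synthetic study reused across the suite.

The heavy artifacts (calibration stats, a cued-grasp training session,
its features and labels) are session-scoped so generation cost is paid
once.  Sizes are scaled to a single-CPU run: 16 channels with 3 hand
channels, 60 s calibration, tens of trials.
"""

from __future__ import annotations

import numpy as np
import pytest

import bciclick as bc

N_CHANNELS = 16
HAND_CHANNELS = (3, 7, 11)


@pytest.fixture(scope="session")
def synth_cfg() -> bc.SynthConfig:
    return bc.SynthConfig(n_channels=N_CHANNELS, hand_channels=HAND_CHANNELS, seed=101)


@pytest.fixture(scope="session")
def spectral_cfg() -> bc.SpectralConfig:
    return bc.SpectralConfig()


@pytest.fixture(scope="session")
def calibration(synth_cfg, spectral_cfg):
    rec = bc.generate_calibration(synth_cfg, duration_s=60.0)
    return rec, bc.fit_calibration(rec, spectral_cfg)


@pytest.fixture(scope="session")
def calib_stats(calibration):
    return calibration[1]


@pytest.fixture(scope="session")
def training_session(synth_cfg):
    return bc.generate_training_session(synth_cfg, n_trials=40, seed=202)


@pytest.fixture(scope="session")
def training_features(training_session, calib_stats, spectral_cfg):
    rec, gt = training_session
    t_ms, X = bc.frames_to_array(bc.stream_features(rec, calib_stats, spectral_cfg))
    return t_ms, X, gt


@pytest.fixture(scope="session")
def labeled_session(training_features):
    """Shift-warped, labeled, and folded version of the shared session."""
    t_ms, X, gt = training_features
    tensor, rel = bc.extract_trial_tensor(t_ms, X, gt.cue_onsets_ms)
    chans = bc.select_modulated_channels(tensor, 3, rel)
    warp = bc.fit_shift_warp(tensor, channels_used=chans)
    labeled = bc.assign_labels(t_ms, gt.cue_onsets_ms, warp.shift_frames, bc.LabelConfig())
    folds = bc.balance_and_fold(labeled, k=10, seed=7)
    return {
        "t_ms": t_ms, "X": X, "gt": gt, "tensor": tensor, "rel_t": rel,
        "channels": chans, "warp": warp, "labeled": labeled, "folds": folds,
    }


@pytest.fixture(scope="session")
def trained_model(labeled_session):
    """One model fit on all balanced folds of the shared session."""
    d = labeled_session
    idx = np.concatenate(d["folds"].fold_indices)
    idx = idx[idx >= 9]
    model = bc.build_model(bc.ModelConfig(input_dim=N_CHANNELS, seed=5, epochs=40))
    model.fit(bc.make_sequences(d["X"], idx, 10), d["labeled"].labels[idx])
    return model
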