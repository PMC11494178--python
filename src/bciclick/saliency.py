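"""Integrated-gradients channel saliency for the grasp classifier.

Attributions of the grasp-class score to each (time step, channel) input
are computed along the straight path from an all-zero baseline (the
rest-state expectation of z-scored features) to the sample, using a
midpoint Riemann approximation of the path integral.  Per-sample maps are
collapsed to channels by the L2 norm over the 10-step history, averaged
over samples and over repeated cross-validation trainings, then min-max
normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttributionMap:
    values: np.ndarray  # (seq_len, n_channels)
    baseline: np.ndarray
    steps: int


@dataclass
class SaliencyVector:
    """Per-channel saliency in [0, 1], keyed by original channel ids.

    Channels the model was not trained on carry NaN ("absent").
    """

    values: np.ndarray  # (n_total_channels,)
    channel_ids: np.ndarray  # ids the model actually used


def integrated_gradients(
    model,
    sample: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 64,
    class_idx: int = 1,
    target: str = "logit",
) -> AttributionMap:
    """Path-integral attribution of the class score to the inputs.

    ``model`` needs ``input_gradient(x, class_idx, target)``; any model with
    that surface (e.g. a linear surrogate) works.  Satisfies completeness:
    attributions sum to F(sample) - F(baseline) as steps grow.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    sample = np.asarray(sample, dtype=np.float64)
    if baseline is None:
        baseline = np.zeros_like(sample)
    diff = sample - baseline
    alphas = (np.arange(steps) + 0.5) / steps  # midpoint rule
    points = baseline[None] + alphas[:, None, None] * diff[None]
    grads = model.input_gradient(points, class_idx=class_idx, target=target)
    attr = diff * grads.mean(axis=0)
    return AttributionMap(values=attr, baseline=baseline, steps=steps)


def channel_attribution(
    model, samples: np.ndarray, steps: int = 64, target: str = "logit"
) -> np.ndarray:
    """Per-sample channel vectors: L2 norm of the attribution map over time.

    samples: (n, seq_len, d) -> (n, d).
    """
    out = np.empty((len(samples), samples.shape[2]))
    for i, s in enumerate(samples):
        attr = integrated_gradients(model, s, steps=steps, target=target)
        out[i] = np.linalg.norm(attr.values, axis=0)
    return out


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def saliency_map(
    model_sets,
    sample_sets,
    steps: int = 64,
    channel_ids: np.ndarray | None = None,
    n_total_channels: int | None = None,
    target: str = "logit",
) -> SaliencyVector:
    """Saliency averaged over cross-validated models and repetitions.

    ``model_sets``: nested iterable [repetition][fold] of trained models;
    ``sample_sets``: matching [repetition][fold] arrays of grasp-labeled
    validation sequences (n, seq_len, d).  The channel means are min-max
    normalized to [0, 1]; with ``channel_ids``/``n_total_channels`` the
    result is embedded into the full channel space with NaN elsewhere.
    """
    vecs = []
    for models, samples in zip(model_sets, sample_sets):
        for model, S in zip(models, samples):
            if len(S) == 0:
                continue
            vecs.append(channel_attribution(model, np.asarray(S), steps=steps, target=target))
    if not vecs:
        raise ValueError("no grasp samples supplied for saliency")
    mean = np.concatenate(vecs, axis=0).mean(axis=0)
    norm = _minmax(mean)
    if channel_ids is None:
        channel_ids = np.arange(len(norm))
    channel_ids = np.asarray(channel_ids)
    if n_total_channels is None:
        n_total_channels = int(channel_ids.max()) + 1
    full = np.full(n_total_channels, np.nan)
    full[channel_ids] = norm
    return SaliencyVector(values=full, channel_ids=channel_ids)


def saliency_from_cv(
    cv_result,
    X_frames: np.ndarray,
    labels: np.ndarray,
    seq_len: int,
    steps: int = 64,
    channel_ids: np.ndarray | None = None,
    n_total_channels: int | None = None,
) -> SaliencyVector:
    """Saliency over a cross-validation result's grasp validation samples."""
    from .model import make_sequences

    model_sets, sample_sets = [], []
    for rep_models in cv_result.models:
        samples = []
        for fold_idx, model in zip(cv_result.val_indices, rep_models):
            g = fold_idx[labels[fold_idx] == 1]
            samples.append(
                make_sequences(X_frames, g, seq_len) if len(g) else np.empty((0, seq_len, X_frames.shape[1]))
            )
        model_sets.append(rep_models)
        sample_sets.append(samples)
    return saliency_map(
        model_sets,
        sample_sets,
        steps=steps,
        channel_ids=channel_ids,
        n_total_channels=n_total_channels,
    )
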