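# Methods

This note documents the models and procedures implemented in `bciclick`,
the parameters that matter, the synthetic-data generator's assumptions,
and the numerical choices made where the design was genuinely open.

## Pipeline overview

The system turns a multichannel electrocorticographic (ECoG) voltage
stream into discrete "brain clicks" that drive a switch-scanning
communication interface:

1. **Calibration.** A 60 s resting recording yields per-(channel,
   frequency-bin) mean and SD of windowed log spectral power.
2. **Features.** A 256 ms window slides in 100 ms steps; per-bin FFT
   power is log-transformed, z-scored against calibration, and the
   z-scores of bins with center frequency in 110–170 Hz (inclusive) are
   summed into one high-gamma (HG) value per channel.
3. **Labeling.** Cue-aligned trials are re-aligned by per-trial integer
   frame shifts (shift-only warping); grasp labels cover a closed
   onset/offset window around each shifted cue; balanced contiguous
   folds support leakage-free cross-validation.
4. **Classifier.** A many-to-one LSTM (25 units) over 10 frames (1 s of
   history) followed by fully connected layers of 10 (eLU) and 2
   (softmax) units predicts rest vs. grasp every 100 ms.
5. **Click detection.** Classifications enter a vote ring buffer
   (window 7, threshold 4 for the speller; 10/10 for the communication
   board); reaching the threshold emits a click, clears the buffer, and
   starts a 1 s lock-out.
6. **Application.** A deterministic switch-scanning state machine
   (rows then columns, 0.67 steps/s, 3 pre-selection rows and 1
   pre-selection column) consumes clicks; two clicks type one letter.
7. **Evaluation.** Sensitivity (% of attempted grasps clicked within
   1.5 s), true/false positive frequencies per minute, click latencies,
   and correct/wrong characters and correct words per minute, with BCa
   bootstrap CIs and rank-sum/Holm comparisons.
8. **Saliency.** Integrated gradients of the grasp score w.r.t. the
   10×C input, L2-collapsed over time, averaged over cross-validated
   models and repeated trainings, min-max normalized to [0, 1].

## Synthetic data generator

No public recordings accompany the decoding problem this package
models, so every stage is exercised on a generator that reproduces the
statistical structure the pipeline assumes — and nothing more:

- **Background**: per-channel Gaussian noise shaped to ~1/f by a fixed
  pinking IIR filter, so log-power statistics differ per bin and the
  per-bin calibration is load-bearing. Filter state persists across
  chunks; batch and streamed generation are continuous.
- **Grasp bursts**: 110–170 Hz band-limited Gaussian noise added to the
  configured hand channels for 800 ms from each movement onset, with
  50 ms cosine ramps. The additive variance is computed from the two
  filters' frequency responses so that in-band power during the burst
  is `hg_effect**2` times resting in-band power (`hg_effect` is an
  amplitude gain; the default 2.0 gives a 4× power increase, the scale
  of a strong motor-cortex HG response). `hg_effect = 1` is the null
  condition used for chance-level checks.
- **Timing**: each trial is a 100 ms Go cue followed by an
  inter-stimulus interval drawn uniformly from 3.0–4.5 s. Movement
  onset lags the cue by a per-trial uniform 150–450 ms reaction delay
  applied identically to all hand channels, making the delay exactly
  recoverable by shift-only warping. The delay distribution is a
  plausible stand-in, not a measured quantity.
- **Low-frequency confound** (optional): a 10–30 Hz component on the
  hand channels whose gain drops to 0.2× from 300 ms before to 800 ms
  after movement onset and rebounds to 1.8× for the following second,
  emulating event-related desynchronization followed by rebound
  synchronization.
- **User model**: in closed loop, the simulated user attempts a grasp
  150–450 ms after the target row/column is highlighted, errs with
  probability `error_rate` (aiming one row/column too far), and always
  corrects erroneous output through the DEL/A-DEL keys.

What the generator does **not** emulate: spatial correlation between
channels, line noise and movement artifacts, non-stationary baselines,
day-to-day drift, or any biophysical cortical dynamics. Passing tests
therefore demonstrate that the pipeline's machinery is correct and
behaves at the expected operating scale on data satisfying its own
assumptions — not that it would reach any particular performance on
real recordings.

## Classifier details

The network is small (15,682 trainable parameters at 128 input
channels under a standard single-bias LSTM parameterization:
`4*((d+h)*h + h) + (h*10 + 10) + (10*2 + 2)`), so the forward pass,
backpropagation through time, Adam, and input gradients are implemented
directly in NumPy. Training uses categorical cross-entropy, 45-sample
batches, 75 epochs, learning rate 10⁻³ (the conventional default for
Adam; not otherwise specified), 30% inverted dropout applied to the
LSTM output and the first FC output (not to recurrent connections), and
He-normal initialization of all weight matrices with zero biases.
Per-epoch training losses are recorded; identical seeds and data give
bit-identical weights, and serialized models reload to bit-identical
outputs.

Streaming prediction emits rest by convention until the 10-frame
history buffer first fills.

## Label window: automated onset/offset

Grasp labels span a closed window `[cue + onset + shift, cue + offset +
shift]`. The onset/offset pair can be pinned (the override path), but
by default it is read off the *aligned trial-averaged HG trace*: the
first and last crossings of 50% of the peak elevation above the pre-cue
median. This matters because the feature timestamp is the analysis
window's trailing edge — the observable HG response lags the physical
burst by up to 256 ms, and a label window tied to ground-truth burst
timing would systematically mislabel boundary frames. Estimating the
window in the feature domain (as one would by eye from the trial
average) aligns labels with what the classifier can actually see; on
synthetic sessions it is the difference between ~0.87 and ~0.94
cross-validated accuracy at the default effect size.

## Voting detector conventions

- A classification timestamped `t` summarizes the 100 ms packet ending
  at `t`. An all-grasp stream starting at packet boundary `t0` yields
  its k-th grasp vote at `t0 + 100k`; with threshold 4 the click fires
  at `t0 + 400` — the 400 ms minimum algorithmic latency, and
  `threshold × 100 ms` in general.
- "Votes surpass the threshold" is implemented as `>=` (the 10-of-10
  and 7-of-7 configurations would otherwise be unsatisfiable).
- On click the vote buffer is cleared and votes are not accumulated
  during the 1 s lock-out. Clearing is not strictly implied by a
  lock-out alone, but without it a long grasp would re-fire the instant
  the lock-out expires, defeating its purpose of suppressing multiple
  clicks per attempted movement. The behavior is configurable
  (`clear_on_click`).
- Offline simulation adds a constant 200 ms on-screen delay to every
  detection (the display/transport overhead an online system would
  measure).

## Model updates from spelling data

When retraining from closed-loop sessions (no Go cue exists), labels
are placed relative to movement onset, and any grasp occurring less
than 3 s (the minimum jittered ISI) after the preceding grasp is
excluded. Frames around excluded grasps are dropped entirely rather
than labeled rest, since labeling genuine burst activity as rest would
poison the rest class.

## Statistics

- **BCa bootstrap** (10,000 replicates, seeded) via
  `scipy.stats.bootstrap`; a constant sample returns the degenerate
  interval with a warning.
- **Rank-sum**: two-sided Wilcoxon rank-sum z with tie correction and a
  0.5 continuity correction, `p = 2Φ(−|z|)`; matches the asymptotic
  Mann–Whitney p-value. Families of comparisons are Holm-adjusted.
- **Event matching** is greedy earliest-click-first with at most one
  click per grasp and an inclusive 1.5 s window; with a 1 s lock-out,
  multi-click ties inside one window are rare, so the greedy rule is
  inconsequential in practice.

## Integrated gradients

Baseline: the all-zero feature history — z-scored features make zero
the resting expectation. Path integral: midpoint Riemann rule, 64 steps
by default (completeness holds to well under 1% at 256 steps; for
linear models any step count is exact). Attribution target: the
pre-softmax grasp logit by default; the softmax probability is
available via `target="prob"`. Saliency vectors mark channels not fed
to the model as NaN, so channel-subset models (e.g. a hand-knob-only
montage) report saliency only over their own inputs.

## Numerical choices and degenerate inputs

- Hann taper before the FFT (rectangular selectable); natural log; log
  power floored at 10⁻³⁰ so an all-zero window stays finite.
- Calibration SDs are floored at 10⁻⁶ (warning logged) so constant
  channels cannot produce infinities.
- Ties break toward the lowest index / earliest time everywhere
  (channel ranking, shift candidates, event matching).
- Shift warping scores each trial against the *leave-one-out* template:
  scoring against a template containing the trial itself biases every
  shift toward zero through noise self-correlation. Non-convergence
  after 50 iterations returns the best iterate flagged
  `converged=False`. Shifts are recentered each iteration (alignment is
  identifiable only up to a global constant) and clipped to ±5 frames.
- The closed-loop simulator quantizes the 0.67 steps/s scan period to
  the 100 ms frame grid (1.5 s per step).

## Problem sizes used in tests

The test and acceptance suites run the full pipeline at reduced scale —
16 channels (3 hand channels), 40–100 trials, 60 s calibration — chosen
so the complete suite trains dozens of models from scratch in about two
minutes on one CPU while keeping per-fold sample counts (~100+ balanced
samples) large enough for stable accuracy estimates. The generator's
defaults (128 channels, 12 hand-knob channels) are what the CLI and
experiment manifests use unless overridden.

## Known limitations

- Headline numbers of a deployed clinical system depend on a
  participant's neural data and are not reproducible here; synthetic
  results only demonstrate correct machinery at a comparable operating
  scale.
- The LSTM implementation is CPU-only and single-threaded beyond BLAS;
  it is sized for this model class (~16k parameters), not for larger
  architectures.
- The suggestion engine is a word/letter frequency model over a small
  packaged corpus — a deterministic stand-in for a neural language
  model behind the same interface.
- The closed-loop user model clicks at most once per scan step and
  recovers from wrong-row selections by selecting the first harmless
  key; real users exhibit richer error behavior.
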