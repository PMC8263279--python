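# Methods

This note documents the models, the synthetic data generator, the numerical
choices and the known limitations of `fnirsdbn`.

## The classification problem

Two binary problems are solved independently per subject: left vs right arm
flexion/extension **execution**, and left vs right **imagery**, from 16-channel
HbO time series sampled at 20 Hz. The analysis unit is a single time point:
the 0–8 s window after each task onset yields 160 samples per trial, each a
16-vector of normalized channel values. With the full protocol (30 trials
per task per session, 3 sessions, 2 classes), sessions 1–2 give a
19200 × 16 training matrix and session 3 a 9600 × 16 test matrix. The
four-class problem is deliberately not attempted; execution and imagery are
always trained separately, and HbR is never classified.

## Synthetic recording generator

No public recordings exist for this paradigm, so `fnirsdbn.simulate`
generates sessions with the statistical structure the analysis assumes:

- **Trial timing.** 2 s cue + 8 s task + 17 s rest + 1 s test cue = 28 s per
  trial; each of the four tasks appears `trials_per_task_per_session` times
  per session in shuffled order (30 by default, hence 90 per task over three
  sessions). Event onsets mark task onset (cue excluded).
- **Hemodynamic response.** A double-gamma kernel, zero at t=0, unit peak,
  main-lobe mode 14 s (dispersion 2.6 s) and a 10 % undershoot at 26 s.
  These defaults were calibrated once so the 8 s boxcar-convolved response
  peaks ≈ 18 s after task onset, the timing observed for slow arm-movement
  HbO responses. When building responses the kernel is rescaled so a single
  trial's noise-free response has unit peak: amplitude parameters are true
  HbO peak scales, directly comparable to the noise amplitudes. Because the
  response outlasts the 28 s trial, consecutive trials overlap, exactly as
  in the real paradigm; the 0–8 s analysis window therefore contains mostly
  the early rise of the current trial plus the decaying tail of the previous
  one, which is one of the things keeping single-time-point classification
  well below ceiling.
- **Task scaling.** Execution responses have unit amplitude scale; imagery
  responses are attenuated by `imagery_amplitude_ratio` (default 0.6);
  channels contralateral to the moving/imagined arm are amplified by
  `contralateral_ratio` (default 1.5) raised to a per-channel exponent (see
  below). HbR is a −0.3-scaled copy of HbO, generated only for realism.
- **Subject profiles.** Each subject (a deterministic function of the study
  seed and subject index) has log-normal channel gains (σ = 0.15), a global
  amplitude scale (σ = 0.05), an HRF peak-delay jitter (± 0.15 s) and a
  per-channel *lateralization topography*: each channel is drawn strongly
  contralateral (exponent ≈ 1.8, p = 0.45), weakly lateralized (≈ 0.3,
  p = 0.10) or reversed (≈ −1.2, p = 0.45), and the gain-weighted contrast
  energy is then equalized across subjects (target 2·(R−1)·√16 in peak
  units). Subjects therefore differ in *where* the left/right contrast
  lives, not in how much of it there is. This is the mechanism behind
  cross-subject transfer structure: per-channel min–max normalization
  removes static gain differences, so only topographic differences can make
  a subject-specific model better on its own subject than on others. The
  mixture proportions were designed during generator calibration so that
  every subject remains classifiable while topographies decorrelate across
  subjects.
- **Noise.** Sinusoids with uniform random phases at 1.1 Hz (cardiac,
  amplitude 0.10), 0.25 Hz (respiratory, 0.10) and 0.10 Hz (Mayer waves,
  0.07 — the only sinusoid inside the analysis band), plus white noise
  (σ = 0.50). All amplitudes are in response-peak units. The budget is
  deliberately white-noise-dominant: after the 0.01–0.2 Hz band-pass the
  surviving white-noise floor (≈ 0.07 in-band) decorrelates across time
  points, whereas Mayer-scale oscillations are nearly constant within an
  8 s window and act as trial-level noise; keeping the trial-correlated
  share small keeps per-subject accuracy estimates stable at the study's
  trial counts.
- **Determinism.** All randomness flows from `SeedSequence` objects keyed on
  (seed, subject, session) and split by purpose (trial order, phases, white
  noise), so regenerating a session is bit-identical and adding channels
  does not reorder trials.

What the generator does **not** emulate: optode geometry and light
propagation, the Beer–Lambert conversion (HbO/HbR are emitted directly),
motion artifacts, non-stationary physiology, session-to-session drift and
habituation. Passing tests on this generator show the pipeline recovers the
class structure it is designed to detect under realistic noise; they do not
certify accuracy levels on real recordings.

## Preprocessing

Third-order Butterworth band-pass, 0.01–0.2 Hz, applied forward and backward
(zero phase) as second-order sections. Epochs are the half-open sample
window [onset, onset + 160). Normalization is per-channel min–max to [0,1],
fitted on training sessions only and applied with clipping to held-out data;
a zero-range channel maps to 0.5. Min–max (rather than z-scoring) is used
because the RBM visible units are interpreted as Bernoulli probabilities and
need [0,1] inputs. Scalers are always per subject, never pooled.

## RBM and CD-1

Visible values in [0,1] are treated as probabilities of binary units (no
Gaussian visible layer). Conditionals include the offsets inside the
sigmoid — `P(hⱼ=1|v) = σ(bⱼ + v·w·ⱼ)`, `P(vᵢ=1|h) = σ(aᵢ + wᵢ·h)` — the
only form consistent with the energy function. CD-1 uses hidden
probabilities for the data-phase statistics, a binary hidden sample to start
the negative chain, and probabilities for the reconstruction statistics.
Updates are momentum-blended velocities (ε = 0.1, α = 0.5), mini-batches of
100 in shuffled order, 10 epochs per RBM, weights initialized N(0, 0.01²),
offsets zero. `exact_marginal` enumerates models up to m + n = 16 and is the
test oracle for the product-of-experts identity and the exact likelihood
gradient. Setting `sample_hidden=False` switches the negative chain to
mean-field, which makes a full-batch training run invariant to sample order
(with the default binary sampling, rng draws are positional and exact order
invariance is not attainable).

## DBN fine-tuning

The stack is 16 → h₁ → h₂ → 2 with mean-field propagation (no sampling) for
classification; the softmax offset is an appended constant-one component.
Fine-tuning minimizes the multinomial cross-entropy with log clamped at
1e-12. Phase 1 optimizes the output weights on frozen features; phase 2
backpropagates through both sigmoid layers (the unused visible offsets stay
untouched). Both phases run Polak–Ribière conjugate-gradient over shuffled
mini-batches (default 1000 rows): per batch up to 3 line searches, each a
backtracking Armijo search started at a step of displacement
`learning_rate` (default 0.3), the accepted step blended into a momentum
velocity (α = 0.5), with a steepest-descent reset whenever the blended
direction stops being a descent direction. The optimizer returns the iterate
with the lowest full-data loss seen at iteration boundaries, so the reported
final loss never exceeds the initial one even though individual momentum
steps may be non-monotone. Default iteration counts are 30 per phase. The
output layer is initialized with small random weights (σ = 0.1): with an
exactly zero output layer no gradient reaches the RBM layers in phase 2,
which can permanently stall training when pretrained features are weakly
label-correlated.

Hidden sizes are selected by 2-fold cross-validation over the Cartesian
product of a candidate array (default [10, 20, 30, 40, 50]); folds are
blocked by trial so the 160 rows of one trial never straddle folds, and
stratified by class. Ties break toward the smaller h₁ + h₂, then smaller
h₁. The bundled study runner defaults to a fixed (10, 10) architecture,
which keeps the multi-seed transfer analysis tractable at desk scale; pass
`fixed_arch=None` to search the grid per subject and paradigm.

## Evaluation

Sample accuracy is the primary metric (each time point is a sample, matching
the 19200/9600-row matrices); trial accuracy by majority vote over the 160
rows of a trial (ties toward class 0) is reported alongside. Per-subject
accuracies are summarized as mean ± population (divide-by-N) standard
deviation — the convention that reproduces the published ±3.73/±3.86
spreads; note that the published movement-column mean (84.35) is
inconsistent with the mean of its own ten per-subject entries (83.35), so
`summarize` always reports computed values. The transfer matrix scores the
imagery model of each subject on every subject's held-out session; its
diagonal holds each subject's own test accuracy.

## Study runner and problem sizes

`run_study`/`run_pipeline` execute simulate → filter → epoch → normalize →
assemble → train → score → transfer with a strict session split (1–2 train,
3 test); no fitted statistic ever sees test data. The reduced-scale study
used by the bundled analyses and the acceptance script — 10 subjects,
10 trials per task per session, fixed (10, 10) architecture, five seeds for
the transfer analysis — was chosen as the smallest configuration that keeps
per-subject training matrices large enough (6400 × 16) for stable training
while a full multi-seed run completes in minutes on one CPU.

## Known limitations

- The generator's subject topography model is a stylized stand-in for real
  inter-subject variability; transfer results quantify the pipeline's
  behavior under that model only.
- CD-1 with 10 epochs leaves first-layer features weakly discriminative;
  classification performance is carried largely by phase-2 fine-tuning.
  This matches the small-architecture regime the pipeline targets.
- Single-CPU, batch (offline) operation only; no streaming/online variant.
- Degenerate inputs: constant channels normalize to 0.5; empty epoch sets,
  mixed-paradigm task pairs, out-of-range RBM inputs and mismatched shapes
  raise explicit errors rather than being coerced.
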