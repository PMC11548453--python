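# Methods

## Problem and approach

A pedometer built into a shoe sole sees each stride twice: a swing burst
(large angular rates, acceleration transients) and a foot-flat phase in
which the sole rests on the ground and the 6-axis IMU reads essentially
gravity plus noise. `solestep` counts steps by detecting that foot-flat
phase with a small recurrent classifier and then extracting one event per
stance under a refractory rule, rather than by thresholding peaks. The
chain is:

1. **Fusion.** A 200 Hz IMU trace (±16 g, ±2000 °/s) and a 60 fps
   annotation table (foot status 0 = moving, 1 = flat, 2 = undetermined;
   activity code) are synchronized via three heel-strike transients (the
   third impact defines t = 0) and fused sample-and-hold into an
   11-column dataset: time, 3-axis accelerations, 3-axis angular rates,
   both Euclidean norms, foot status, activity.
2. **Data reduction.** Each of the 8 candidate channels is scored by its
   Pearson correlation with the binary foot-flat label over the pooled
   cohort; channels with |r| < 0.1 are dropped. On the synthetic cohort
   (as on real sole-IMU data) this retains the gyroscope norm, the
   acceleration norm and the vertical acceleration axis.
3. **Classifier.** A many-to-one stacked LSTM consumes a 125 ms window of
   anterior samples of the retained channels and emits P(foot flat) for
   the window's final sample. Default architecture: 2 layers × 32 units,
   tanh candidate/output activation (gates sigmoid), dropout 0.2 on the
   final state, a single sigmoid output unit. Training: Adam at 1e-2,
   batch 1024, binary cross-entropy, at most 100 epochs with early
   stopping (patience 10 on validation loss, 5-minute wall-clock budget),
   best-validation weights restored. The network is a compact NumPy
   implementation (forward + backpropagation through time); its per-layer
   parameter count is the standard 4·(u·(c+u)+u).
4. **Step extraction.** The thresholded probability stream (≥ 0.5 → flat)
   is scanned left to right; each 0→1 onset registers a step unless it
   falls within the rest delay (RD) after the previously registered
   onset. RD is selected by sweeping 25–1000 ms in 25 ms steps (40 grid
   points) against the observed step counts; ties break toward the
   smaller delay.
5. **Evaluation.** Subject-wise 7-fold cross-validation (3 subjects per
   fold from 21) or a single 18/3 split. Two criteria: MAPE_DL compares
   flat-labeled sample counts of the prediction and the annotation;
   MAPE_G compares final step counts.

## Synthetic cohort

The study protocol this package targets uses a non-public multi-activity
dataset, so a first-class simulator (`gait_synth`) generates statistically
matched trials: a scripted track of 191 steps per subject — 11 stair
descents, 40 walking steps split over three speeds, 40 running steps, 30
each of stomping / high knees / butt kicks, a 10-step transition walk —
interleaved with standing rests and preceded by a 3-heel-strike sync
prelude. Per-foot cadences span 40–80 steps/min (periods 0.75–1.5 s) and
flat fractions 0.16–0.45 of the step period, so the flat share of
determined samples lands near 0.40.

Each step is synthesized as: a swing with a steep sole-pitch excursion
(θ(s) = θ_max·√sin(πs), so the sole leaves the ±3° flat band within about
one sample), an angular-rate burst along a random per-step 3-D axis,
gravity tilt plus motion acceleration with a random per-step horizontal
direction, and a ~30 ms heel-strike transient; then a quiescent flat
interval. The burst magnitude is a clipped half-sine floored at the pitch
rate |dθ/dt| implied by the emitted angle trace — the gyroscope norm can
never be below the rotation rate that produces the sole angle, so the
steep lift-off and landing edges carry large rates and the flat/moving
boundary is as crisp in the signal as it is in the labels. Gaussian
noise is added to all six channels and signals are clipped to the sensor
ranges. Subject heterogeneity: cadence multiplier ~ N(1, 0.08),
amplitude multiplier ~ N(1, 0.3) clipped to [0.5, 1.7], per-step
log-normal amplitude jitter (σ = 0.4), and per-subject noise floors.

The annotation emulator samples the sole angle at 60 fps, thresholds at
3° (|angle| < 3° → flat; exactly 3° counts as a transition) and relabels
contiguous runs (geometric, mean 0.25 s) as undetermined until ≈ 9.7% of
frames carry label 2 — the ratio seen in frame-by-frame video labeling of
this kind of protocol. Runs are contiguous because camera occlusion is.

**Calibration.** The free shape parameters (burst plateau gain, motion-
acceleration-to-impact ratio, swing-angle amplitudes, jitter, noise
floors) were fixed once so that the pooled channel/label correlation
magnitudes on the default 21-subject cohort match the values reported for
real sole-IMU data: |r| ≈ 0.64 (gyro norm), 0.41 (acc norm), 0.16
(vertical acc), with every individual gyro axis below 0.1. The axis
decorrelation is produced by randomizing each step's rotation axis and
horizontal heading — the generator reproduces the phenomenon without
claiming a mechanism. Note the signs: both norms are *low* during flat,
so their signed point-biserial correlations are negative; rankings and
reports quote |r|, as correlation-matrix figures conventionally do.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: biomechanically coherent kinematics (the swing
burst is a shaped sinusoid, not a leg model), slopes, turns, left-foot
asymmetries, sensor bias drift or temperature effects, soft-tissue
artifacts, and genuinely ambiguous stances (shuffling, weight shifts).
The synthetic classes are cleanly separable given the gyro norm, which is
why held-out step error can reach zero here while real-data error cannot.

## Undetermined labels

Undetermined (status 2) samples are excluded from training windows (a
window whose final sample is undetermined is dropped; earlier samples
inside a window are kept — sensor data exists regardless of camera
visibility) and from MAPE_DL. Step counting, however, runs on a
deployment-style stream with one prediction per IMU sample, occluded
spans included: a deployed counter has no labels, and compacting the
stream to determined samples would merge stances whenever an occlusion
run covers a whole swing, putting a floor of several percent under the
step-count error that has nothing to do with the model.

## Numerical and design choices

* Loss/optimizer: binary cross-entropy with a single sigmoid unit; Adam
  (β₁ 0.9, β₂ 0.999, ε 1e-7). Neither is dictated by the architecture
  description; both are the standard choice for it.
* Initialization: Glorot-uniform weights, zero biases except forget-gate
  biases at 1. Cell states are clipped to ±50 as a relu-activation guard.
* All arithmetic is float32; training is deterministic given the seed and
  thread count.
* The window label is the status of the window's final sample (causal
  prediction); window length w = round(window_ms · fs / 1000).
* Normalization: per-channel z-scoring fitted on training windows only;
  zero-variance channels clamp to scale 1 with a warning.
* Decision threshold 0.5, inclusive (P = 0.5 → flat); exposed in config.
* Training stride thins training windows only (default 1; 4 in the fast
  profile and the reduced-scale experiments); prediction is always per
  sample.
* The refractory comparison is done in sample units (onset-index
  difference vs rd · fs / 1000) to avoid float-time edge cases at exact
  multiples of the delay.
* Rest-delay tie-break: smallest delay among minimizers. On the default
  synthetic cohort the trained classifier's streams are crisp enough that
  the sweep's zero-error plateau extends down to the smallest grid value,
  which the tie-break then selects; noisier streams move the selected
  delay up into the few-hundred-millisecond range.
* Cross-validation reuses the held-out fold as the early-stopping
  validation set by default, reproducing the study design it mirrors;
  `nested_val=True` instead carves a validation subject out of the
  training folds for a leakage-free variant.
* Hyperparameter search: stage 1 spends ⌈25%⌉ of the trial budget on
  uniform random draws from the grids; stage 2 perturbs the incumbent
  best, each parameter jumping to an adjacent grid value with probability
  equal to a temperature decaying linearly 1.0 → 0.2. This kernel
  reliably recovers a stub objective's optimum on low-dimensional
  subspaces (the recovery property is tested on a 3-parameter subspace);
  exact grid recovery over all nine parameters within a 50-trial budget
  is not a property of so simple a kernel, and the search is meant to
  find competitive regions, not the exact grid point.
* Grid realization (the design space is published as ranges + counts
  only): units {16, 32, 64, 96, 128}, layers {1, 2, 3}, dense flag
  {off, on}, dense units {8, 16, 32, 48, 64}, window 25:25:250 ms,
  dropout 0.1:0.1:0.5, activations {relu, sigmoid, tanh}, learning rate
  20 log-spaced points in [1e-4, 1e-2], batch {64, 128, 192, 256, 512,
  1024, 2048}. All grids are explicit configuration and overridable.

## Problem sizes used by the shipped experiments

The single-split experiment (also what `scripts/acceptance.py` runs)
simulates the full default cohort — 21 subjects × 191 steps ≈ 900k IMU
samples — trains on 18 subjects at stride 4 (~190k windows of 25 × 3)
under the standard early-stopping rules, and predicts per-sample on the 3
held-out subjects. Unit and property tests use miniature tracks (10–20
steps) and models (4–8 units) so the suite stays interactive.

## Known limitations

* The classifier is CPU-bound NumPy; it is meant for studies of this
  pipeline's logic at cohort scale, not for large-scale training.
* The simulator's separability means reported synthetic errors bound the
  pipeline's plumbing, not real-world accuracy.
* Only the instrumented (right) foot is modeled; whole-body step counts
  assume symmetric doubling upstream of this package.
* MAPE_DL counts flat-labeled samples (not flat phases); the metric is
  isolated in one function so a phase-count variant can be swapped in.
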