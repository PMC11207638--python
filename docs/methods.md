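# Methods

This note documents the models and procedures implemented in `adlwild`, the
choices made where the underlying method leaves room, and what the synthetic
experiments do and do not demonstrate.

## Ingestion and windowing

Recordings are long-format CSVs (one row per sample and hand) relabeled onto
a closed vocabulary of seven ADLs plus `NULL` before any processing. The
relabeling map is total: clapping and unknown free-text activities collapse
to `NULL`, stair climbing/descending counts as walking, and
electric-toothbrush brushing counts as `NULL` because its movements do not
resemble manual brushing. Timestamps are resampled to a uniform grid by
linear interpolation (labels take the nearest raw sample). The sensor rate
is a parameter; the default is **50 Hz**, a typical wrist-IMU rate — the
method itself does not prescribe one.

Windows are 1 s long with 75% overlap (0.25 s stride). The number of full
windows in a stream of duration T is `floor((T − w)/stride) + 1`. Each
window's label is the majority of its per-sample labels; ties break in favor
of a non-`NULL` activity (the rare classes are the signal of interest), and
among tied activities the label at the window's center sample wins. The same
rule rasterizes ground truth onto the prediction grid for scoring, so
reference and predicted streams are strictly comparable.

## Features (106 per window)

Seventeen features per accelerometer axis per hand, two per hand. Several
of the names in the feature list admit more than one formalization; the
definitions used here are:

* **Average jerk** — mean absolute first difference × sample rate (a
  first-order approximation of the derivative of acceleration).
* **Average/Std height** — mean and standard deviation of the signal value
  at detected peaks; 0 when there are no peaks.
* **Energy** — mean squared mean-removed sample (the signal variance).
* **Entropy** — Shannon entropy of the normalized one-sided DFT magnitude
  distribution.
* **Peaks/valleys** — local extrema with prominence ≥ 0.1 × the window's
  standard deviation (so a flat window has none); the *average* and *std of
  the number* of peaks (valleys) are taken over the window's four equal
  non-overlapping quarter segments, which gives those summary statistics a
  well-defined population.
* **Spectral centroid / spread / rolloff** — computed on one-sided DFT
  magnitudes with the DC bin excluded, in bin units `k = 1..N`:
  `C = Σ k·X(k)/Σ X(k)`, `S = sqrt(Σ (k−C)²X(k)/Σ X(k))`, rolloff = the
  smallest `k` accumulating 85% of the total magnitude. An all-zero
  spectrum returns (0, 0, 1) rather than NaN.
* **Axis overlap** (per hand) — the number of pairwise crossings among the
  three axis traces divided by the window duration; crossings are a direct,
  unit-free measure of how much the axes intertwine.
* **Fractal dimension** (per hand) — box-counting estimate on the Euclidean
  norm of the 3-axis signal, rescaled to the unit square, with the polyline
  upsampled 4× so segments (not only samples) determine box occupancy. The
  slope of log N(ε) against log(1/ε) is fit over a dyadic ε grid and clamped
  to [1, 2]; constant or shorter-than-8-sample signals return 1 by
  convention.

Score ties in the postprocessor and all feature computations are
deterministic given the input; two identical windows always produce
identical rows.

Standardization: z-scoring with training-split statistics is applied inside
the NB and SVM models (scale-sensitive); tree models consume raw features.

## Imbalance treatments

Applied to the training split only, after feature extraction — never to
validation or evaluation data.

* **RUS** — the majority (`NULL`) class is sampled without replacement down
  to exactly the total non-majority count.
* **Ratio-preserving ROS** — minority classes are duplicated with
  replacement until their total equals the majority count; the integer
  targets come from largest-remainder apportionment, which hits the total
  exactly with at most one unit of ratio distortion per class. Fully
  balanced oversampling is deliberately not used: at imbalance ratios in
  the hundreds it would encode an absurd equal-frequency prior.
* **CSL** — class weights `w_c = n_total / (n_classes · n_c)`. Gaussian NB
  takes no weights and is excluded from cost-sensitive trials.

## Window models

Gaussian Naive Bayes, Random Forest (100 trees, max depth 30), SVM with RBF
kernel, XGBoost (100 rounds, max depth 30, histogram tree method). Where
the method's description stops, library defaults are kept and logged:
SVM uses C = 1 and variance-scaled gamma; XGBoost uses its default learning
rate and the multi-class softmax objective. All models expose a seed and
refuse feature matrices whose column schema differs from training.

## Context-based prediction correction

Each prediction is replaced by the weighted-majority label of the `ws`
predictions around it (weight functions W1–W5; natural log — the corrected
label is invariant to the base since scores scale by a positive constant).
The context midpoint is `⌊ws/2⌋ + 1` (1-indexed) and the distance is
`d = |i − midpoint|`: a signed-offset variant exists behind a
compatibility flag, but an asymmetric triangular weight would contradict
the definition of `d` as distance from the center, so the absolute form is
the default. Negative weight arguments (even `ws` at the extreme offset)
clamp to zero: scores accumulate evidence and negative evidence is
undefined.

Tie-breaking: highest score wins; score ties (detected with a 1e-9
*relative* tolerance, so that sums of logs that factor identically — e.g.
ln 2 + ln 3 vs ln 6 — tie under any base) break toward the higher raw count
in the window, then toward the earliest first appearance.

Two stream modes:

* **centered** (default) — `P′[t]` is the correction of the window centered
  at `t`; positions whose full context would leave the stream pass through
  unchanged, and a context longer than the stream passes the whole stream
  through with a warning. This alignment is what event scoring against
  ground truth requires.
* **literal_streaming** — the online form: the first `ws` outputs pass
  through, then each output is the correction of the trailing context
  window, reproducing the deployment lag. A context of one prediction is
  the identity in both modes.

`ws` is specified in seconds of stream and converted by
`round(ws_seconds/stride)`; 160 s at the default stride is 640 predictions.

## Event-level evaluation

Events are maximal same-class runs (half-open, frame units). Overlap means
at least one shared frame; a configurable minimum-overlap fraction exists
but is off by default. Per ground-truth event: Deletion if no overlapping
prediction, Fragmented if overlapped by ≥ 2 predictions, Merged if an
overlapping prediction also overlaps another ground-truth event, FM if
both, else Correct; the prediction-side categories mirror this and the two
Correct tallies agree by construction (asserted after every scoring).
Pooled "event-level" numbers sum category counts across activity classes
(micro-pooling) before applying the P/R/F1 formulas; per-class values are
always also emitted, as are window-level macro precision/recall/F1 over all
classes including `NULL`. Zero-denominator convention: a metric is 1 when
both streams contain no events and 0 when only the denominator's side is
empty.

## Synthetic data generator

The generator exists to exercise the pipeline under the right *statistics*,
not to be biomechanically real. Each activity class is an idealized
signature: an oscillation at a class-specific frequency (0.9–4.5 Hz band)
with class-specific amplitude and per-axis mixing, rendered on a dominant
wrist (attenuated ×0.3 on the other, or on both wrists for bimanual
activities), with per-event frequency (±0.25 Hz) and amplitude (±30%)
jitter. Events are placed by a per-class Poisson process with log-normal
durations and a non-overlap constraint; unplaceable events are dropped
under an attempt cap. The `NULL` background is white sensor noise plus
gravity plus:

* **distractor bursts** — oscillations with random frequency/amplitude/
  mixing, biased toward the low-frequency band where everyday arm movement
  lives; and
* **confuser bursts** — *short* motions rendered through the same signature
  path as a confusable class but labeled `NULL` (a sip-like arm raise
  without drinking). Where confuser time exceeds class time, a prior-driven
  classifier correctly prefers `NULL` in that feature region, which is the
  mechanism that suppresses rare-class recall until oversampling or
  weighting shifts the boundary.

Consumption-style activities (drinking, taking medication) additionally use
a gesture duty cycle: the labeled span is mostly idle with brief
characteristic gestures, so most of their windows are genuinely
indistinguishable from the background — reproducing the known failure mode
of window classifiers on high-intraclass-variability ADLs.

Two profiles ship:

* **default** — 9 participants, 3–12 h each, 50 Hz; per-class event rates
  derived from target imbalance ratios of 45–510 so the dataset mirrors the
  study-scale imbalance structure.
* **demo** — 5 participants, 1.6–2.4 h each, 20 Hz, with compressed
  imbalance (average achieved IR ≈ 55) and raised event rates. This is the
  profile used by the end-to-end tests and the acceptance script: at a few
  hours of data, study-scale ratios would leave rare classes with zero
  events, making event-level statistics meaningless. The cost of the
  compression is that absolute numbers are not comparable to a study-scale
  run; only the qualitative pattern is.

`corrupt_predictions` perturbs label streams directly (activity→NULL
misses, geometric-length spurious insertions at a calibrated start rate,
fragmentation holes), so the postprocessor and metrics can be exercised
without training a model.

## Experiment protocol

Whole sessions (contiguous streams) are assigned greedily, largest ADL
volume first, to train/validation/evaluation splits (70/20/10) minimizing
the summed absolute deviation of per-class ADL hours from the targets; a
repair pass guarantees every split is non-empty, and sessions of one
participant can be forced to move as a unit (strict user independence).
The model grid trains each (preprocessing × family) cell once, caches
validation predictions, and sweeps the postprocessing grid (by default 24
context sizes, 10–240 s in steps of 10 s, × 5 weight functions = 120
configurations) at the prediction level; selection is by pooled event-level
F1 with ties toward the smaller context. The evaluation split is touched
once, by the selected configuration.

## Problem sizes and variance

The end-to-end tests and the acceptance script run the demo profile:
~10 h of simulated data, ~145 k windows, two XGBoost fits, one W4/160 s
correction per arm. This is the scale at which the whole suite completes in
minutes on one CPU. At this scale the held-out participants contain on the
order of 15–30 events, so event-level metrics are coarse (one event is
3–7 percentage points) and the directional preprocessing/postprocessing
comparisons are seed-sensitive: across seeds the oversampling
recall-vs-precision trade and the correction's precision gain hold in most
but not all draws (ties occur when baseline recall saturates). The seeded
tests document one fixed draw; they validate that the pipeline reproduces
the qualitative pattern, not any particular magnitude, and nothing at this
scale should be read as an estimate of performance on real recordings.

Real-data features the generator deliberately omits: orientation drift and
gravity leakage between axes, heteroscedastic and autocorrelated noise,
activity transitions (events start and stop instantaneously), behavioral
rhythms in event timing, and any gyroscope content. Passing tests therefore
demonstrate correctness of the machinery and the direction of the
imbalance/context effects, not field accuracy.

## Numerical conventions

* Spectral quantities are in DFT bin units, DC excluded.
* Score-tie tolerance 1e-9 (relative), see above.
* All randomness flows through explicit integer seeds (numpy Generator);
  resampling, simulation, and model fits are reproducible bit-for-bit given
  the seed.
* Degenerate inputs: empty streams correct to empty streams; a stream
  shorter than one window yields an empty window list; an all-zero spectrum
  returns the (0, 0, 1) fallback; constant signals have fractal dimension 1
  and no peaks.
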