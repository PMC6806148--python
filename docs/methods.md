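# Methods note

This note records the exact numerical conventions, modeling assumptions and
scope of `adlfusion`. Everything stated here is implemented and covered by the
test suite; no empirical claim is made beyond what `scripts/acceptance.py`
computes.

## Timeline conventions

- All timestamps are integer milliseconds. Windows and annotation intervals
  are half-open `[start, end)` everywhere; a sample at `t = end` belongs to
  the next window.
- A stream's span is `[t_first, t_last + nominal_period)`.
- Inertial window grid: length `L = 1000 ms`, step `S = L·(1 − overlap)` with
  overlap 0.5 or 0.75; windows are `[k·S, k·S + L)` for `k = 0 …
  ⌊(span − L)/S⌋`, only windows fully inside the span are produced.
- Vision windows group 10 consecutive frames with stride 5; a window's end is
  the last frame's timestamp plus one frame period.
- Matching: a vision window starting at `ts` is paired with the inertial
  window having the smallest start `ts′ ≥ ts` (so `0 ≤ ts′ − ts < S`);
  vision windows with no later inertial window are dropped.

## Inertial features (42 per wrist, 84 per window)

Per axis (x, y, z): arithmetic mean; median; *population* standard deviation
and variance (denominator `N`); interquartile range with linear quantile
interpolation; mean absolute deviation around the mean; Fisher *excess*
kurtosis (0 for constant signals); time-domain entropy of a 10-bin histogram
over the window's own range, natural logarithm; spectral energy; spectral
entropy; DC/mean component. Plus the three pairwise Pearson correlations
(0 for constant axes), a gravity estimate and three orientation angles.

Spectral conventions (per axis, `X_k` = unnormalized DFT of the `N` samples):

- `mean_dc = X_0 / N` (equals the arithmetic mean).
- `energy = Σ_{k≥1} |X_k|² / N` — DC excluded, so a constant signal has zero
  energy. Parseval under this convention: `Σ_t a_t² = N·mean_dc² + energy`.
- `entropy_freq`: Shannon entropy (natural log) of the non-DC power spectrum
  normalized to a probability distribution; 0 when there is no non-DC power.
  A pure sinusoid with an integer number of periods gives `ln 2` (its power
  sits in the two conjugate bins).

Gravity is a first-order exponential low-pass `g_t = α·g_{t−1} + (1−α)·a_t`
with `α = 0.9`, seeded at the window's first sample. Orientation angles are
`arccos(g_i / ‖g‖)` per axis. Windows with fewer than 4 samples are dropped.

## Vision features

The hand is the highest-confidence box of the hand class (`person` by
default) with confidence ≥ 0.5; ties break by larger area, then smaller
`x_min`. The per-frame feature for object class `c` is
`max over instances of area(hand ∩ object) / area(object)` — an asymmetric
overlap, not IoU (an IoU variant is provided as `overlap_iou`). Frames
without a hand get the all-(−1) sentinel vector. Window features are the
arithmetic mean over the 10 frames, *including* sentinels by default
(`sentinel_mode="exclude"` averages only hand-bearing frames and yields the
sentinel vector only if no frame has a hand).

## Alignment

The per-axis median over the first `min_still_ms` (default 1000 ms) of a
stream is its stillness baseline. Motion starts at the first of 3 consecutive
samples whose acceleration vector deviates from that baseline by more than
`still_threshold` (default 0.5 m/s², Euclidean norm). The full-vector
deviation is used rather than a magnitude-only criterion because motion
orthogonal to gravity leaves the magnitude nearly unchanged. The vision
counterpart is the first of 3 consecutive frames containing non-hand
detections. Offsets are `start(reference) − start(source)`; adding a source's
offset to its native timestamps lands it on the reference timeline. Streams
are then trimmed to `[max(starts), min(ends))`. Streams without a usable
stillness prefix raise and require manual offsets.

## Labels, fusion and evaluation

- A window's label is the annotation class with the largest intersection,
  provided it covers ≥ 50 % of the window (`min_cover`); otherwise `none`.
  Compound labels (`verb-object1-…`) can be reduced to their verb token.
- Early fusion concatenates `[84 imu | per-object vision]`; late fusion
  (stacking) trains a 100-tree random forest on the imu block and an L2
  logistic regression (`C = 1`) on the vision block, appends each model's
  class probabilities to its own block, and trains a 100-tree random-forest
  meta classifier on the concatenation (meta input width
  `84 + C + V + C` for `C` classes and `V` object features). Base
  probabilities are in-sample by default; `prob_mode="out_of_fold"` uses
  5-fold out-of-fold probabilities during fitting.
- De-overlap subsampling keeps every other window (50 % overlap grids) or
  every fourth (75 %), making retained windows pairwise disjoint so no raw
  sample can appear on both sides of a split.
- Protocols: repeated stratified k-fold CV (fold redraw per repeat, seeded);
  fixed cross-subject splits with optional random oversampling of training
  minority classes to the majority count; 80/20 stratified split with an
  inner 5-fold grid search on macro F1. Per-class precision/recall/F1 use the
  zero-division-is-zero convention.

## Synthetic generator

The generator is the package's study instrument; its defaults define the
study conditions and are not tuned per experiment.

- Cohorts: 2 subjects × 6 sessions by default, alternating two scripted
  activity sequences over six ADL classes. Activity durations (2–4 s) and
  inter-activity gaps (1–2 s) are quantized to 200 ms; sessions start with a
  5200 ms stillness lead-in. Wrists sample at 50 Hz, frames at 25 fps.
- Motion: per-class sum-of-cosine templates per wrist and axis, phase-locked
  to the activity onset so each activity begins with a full-amplitude jump
  (an onset spike), superimposed on gravity `(0, 0, 9.81)` plus Gaussian
  sensor noise (default sd 0.1 m/s², a resting-MEMS noise floor).
- Vision: a fixed hand box; each active object is placed so that its
  hand-overlap equals a draw from a per-class Beta law (or a constant),
  realized exactly by construction. Detector noise: hand-miss probability,
  false-positive rate, box-coordinate jitter, confidences uniform in
  [0.6, 1.0].
- Clock offsets are injected per source and written as ground truth.
- Seeding: `np.random.SeedSequence(entropy=seed, spawn_key=(subject,
  session))` — sessions are independent, bit-reproducible streams; cohort
  directories carry a SHA-256 manifest.
- Confusable design: 4 classes where classes 1–2 share a motion template but
  use disjoint objects and classes 3–4 share an object but have distinct
  motion spectra. Durations are fixed at 3000 ms and gaps at 1000 ms, so with
  the 5200 ms lead-in every activity boundary is congruent to 200 mod 1000
  and every matched inertial window overlaps actual activity motion — which
  is what makes noise-free macro F1 = 1.0 achievable and therefore a sharp
  correctness criterion.

## Limitations

- The generator's motion templates are stationary sums of cosines; it does
  not model tremor, posture drift, gyroscope channels, or realistic detector
  confusions between visually similar objects.
- The alignment detector requires a stillness lead-in and a detectable onset;
  recordings without one need manual offsets.
- Evaluation numbers produced by this package characterize the pipeline on
  its own synthetic cohorts only; no claims are made about performance on
  external recordings.
- Only the accelerometer channel and 2-D box geometry are modeled; no raw
  video or image processing is included.
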