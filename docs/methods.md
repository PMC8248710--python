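# Methods

## Problem and signal model

The package detects four kinds of respiratory sound events in 15-s,
4-kHz, 16-bit mono lung-sound recordings: inhalation (I), exhalation
(E), continuous adventitious sounds (CAS; wheeze W, stridor S, rhonchus
R, pooled into one class C for detection), and discontinuous
adventitious sounds (DAS; crackles, class D).  Detection is phrased as
per-frame sequence labeling: a recording becomes 938 time frames (16 ms
apart), a detector scores each frame in [0, 1] per task, and
postprocessing turns thresholded frame runs into events with onset and
offset times.  Two evaluations follow: frame-level ("segment")
classification, and event-level matching by Jaccard index.

## Feature extraction

All parameters below are package defaults and match the benchmark
protocol the framework implements.

* **High-pass filter.** 10th-order Butterworth, 80 Hz cutoff, applied
  forward–backward (`sosfiltfilt`).  The zero-phase choice is ours: the
  protocol names only order and cutoff, and a causal pass would delay
  event onsets by a signal-dependent group delay, which would bias the
  event-time labels.  The doubled effective order makes the stop band
  (≤ 60 Hz, mains hum and most heart-sound energy) ~2× deeper in dB;
  the pass band is flat either way.
* **STFT.** Hann window of 256 samples (periodic form), hop 64, no FFT
  zero-padding beyond the window.  A 60,000-sample signal is
  center-padded by 128 zeros per side, giving exactly
  1 + ⌊60000/64⌋ = 938 frames of 129 bins (0–2000 Hz, 15.625 Hz/bin);
  frame *i* is centered at *i* × 0.016 s.  Center padding is the only
  framing convention that produces the canonical 938 frames.
  Log magnitude is 20·log₁₀(|X| + ε), ε = 10⁻¹⁰ (the floor bounds the
  all-zero-signal output at −200 dB).
* **MFCCs.** 40 triangular mel filters (HTK mel scale,
  2595·log₁₀(1 + f/700), unnormalized triangles) spanning 0–4000 Hz on
  the same 938-frame power spectrogram, log, orthonormal DCT-II, first
  20 coefficients *including c₀*, plus Δ and Δ² by width-9 regression
  with edge replication → 60 columns.  Two conventions are ours because
  the protocol leaves them open: the nominal 0–4000 Hz band extends
  past the 2-kHz Nyquist, so the top filters receive no energy and
  produce constant (floor) columns — harmless, as normalization maps
  them to 0 and the delta regressions ignore constants; and the MFCCs
  are computed on the *filtered* signal, like every other feature.
* **Band energies.** Sums of spectral power (squared linear magnitude —
  "energy" is a power quantity, so the log values are not summed) over
  bins whose center frequency falls in [0, 250), [250, 500),
  [500, 1000) Hz, and the full 0–2000 Hz axis.  Half-open membership
  avoids double-counting the shared 250/500/1000 edges; the fourth band
  includes every bin and therefore dominates the sub-bands.
* **Normalization.** Columns of the concatenated 938 × 193 matrix
  (129 | 60 | 4) are independently min–max scaled to [0, 1] *per
  recording*; constant columns map to 0.  Per-recording scaling is an
  interpretation (the protocol does not say whether statistics were
  pooled over the training corpus); it requires no dataset pass, yields
  the stated [0, 1] range exactly, and makes feature extraction a pure
  per-recording function.

## Target construction

Frame *i* is positive for a task iff its center time lies in the closed
interval [onset, offset] of any event of that task's classes (CAS pools
W, S, R).  Closed-interval membership follows the framework's frame
accounting (an event spanning [1.0, 2.0] s sets frames 63–125, i.e. 63
frames); the choice only matters when a frame center coincides exactly
with an event boundary.  Targets for CNN-fronted models (469 half-rate
frames) are built by pairwise max-pooling, so an event visible in
either constituent frame survives the 2× reduction — plain subsampling
could drop events shorter than two hops.

## Detector architectures

The backbone shared by all twelve variants is: two stacked recurrent
layers → time-distributed Dense(32, ReLU) → Dense(1) (sigmoid at
inference; the training loss consumes logits).  Recurrent widths:

| family | units per direction and layer |
|---|---|
| LSTM / GRU (unidirectional) | 128 |
| BiLSTM / BiGRU | 128 (256 across directions) |
| SIMP BiLSTM / SIMP BiGRU | 64 (128 across directions) |

Weight shapes follow the TensorFlow/Keras conventions (LSTM: one 4H
bias; GRU: the CuDNN-compatible `reset_after` form with separate input
and recurrent 3H biases).  Under this reading the built models count
exactly the published totals — LSTM 300,609; GRU 227,265; BiLSTM
732,225; BiGRU 552,769; SIMP BiLSTM 235,073; SIMP BiGRU 178,113 — and
the test suite asserts these counts against the constructed weight
arrays.  This layer reading was *reconstructed from the published
parameter counts* (the architecture figures are not machine-readable in
our source); it is the unique consistent solution we found, and the
eight CNN-fronted totals are also reproduced by the same recurrent
stack and head on top of a front end with 68,224 parameters emitting
6,208 features per frame (64 channels × 97 frequency units).

**CNN front end.**  The front end's internal kernel/channel layout is
genuinely underdetermined: a brute-force search found 2,154
configurations meeting the 68,224-parameter budget with the right
output shape, and nothing in our source selects among them.  The
package therefore ships a plain default — Conv2D 3×3, 1→16 channels,
'same' padding, ReLU; Conv2D 3×3, 16→64, stride 2×2; flatten — which
halves the time axis 938 → 469 and emits the same 6,208 features per
frame but has 9,440 parameters.  CNN-model parameter counts are
reported as advisory: each differs from the published total by exactly
the 58,784-parameter front-end gap (e.g. CNN-GRU 2,546,465 here vs
2,605,249 published).  Output length (469) and everything downstream
are unaffected.

**Training.**  Adam, initial learning rate 10⁻⁴; learning rate ×0.2
when validation loss has not strictly decreased for 10 consecutive
epochs; stop after 50 consecutive epochs without improvement;
best-validation weights restored.  The two patience counters run
independently, and "improvement" is a strictly lower validation loss
with zero tolerance — the plainest reading of the protocol.  The loss
(per-frame binary cross-entropy) and batch regime (batch 32, shuffled
per epoch under the run seed) are our choices where the protocol is
silent; BCE is the standard loss for per-frame sigmoid labeling.
Initialization is Glorot-uniform (forget-gate bias 1) under a seed, and
the layers are implemented directly in numpy with hand-derived BPTT —
verified against central-difference gradients to ~10⁻⁷ relative error
in float64.  Everything is deterministic given (seed, data).

**Cross-validation.**  Recordings carry a subject/day group key; folds
are formed by shuffling groups under the seed and greedily placing each
(largest first) into the currently smallest fold.  No group ever spans
two folds — recordings captured in one session are too similar for an
honest split — and fewer groups than folds is an error.

## Postprocessing

Frames with score ≥ θ (default 0.5) form maximal runs; a run becomes an
event spanning [first center − hop/2, last center + hop/2], clamped at
0.  Two consecutive events merge when the gap is strictly below
T = 0.5 s *and* their spectral energy peaks differ by strictly less
than P = 25 Hz; both inequalities are strict, following the protocol's
wording ("smaller than", "below").  The energy peak of an event is the
bin-center frequency maximizing mean linear power over the event's
frames on the *pre-normalization* spectrogram (normalization distorts
per-column scales), ties going to the lowest bin.  Scanning is
left-to-right; a merged event's peak is recomputed and it may merge
again with its successor; the pass repeats until the list is stable.
The fixed-point iteration is ours: it makes merging idempotent, which a
single pass is not (a recomputed peak can unlock a preceding pair).
After merging, events strictly shorter than 0.05 s are deleted.  Merge
then delete is *not* idempotent as a chain in rare configurations —
deleting a short event can bring its neighbours within T — and the
package keeps the prescribed order rather than iterating the chain.
The same postprocessor applies to all four tasks (merging is motivated
by split inhalations, but the mechanism is task-agnostic; per-task
disabling is a config choice).

## Evaluation

Segment metrics (accuracy, PPV, sensitivity, specificity, F1) come from
frame-wise confusions, computed per recording and macro-averaged, with
pooled micro variants also reported; 0/0 ratios are undefined and are
excluded from macro averages rather than zero-filled, so recordings
with no events of a class do not bias the mean.  ROC/AUC pools frames
across the evaluated recordings and uses the trapezoidal rule; the test
suite checks it against the Mann–Whitney rank statistic to 10⁻⁹.

Event matching computes the Jaccard index (interval intersection over
union) between each detected and each true event, greedily accepts
pairs in descending JI order as TPs when JI > 0.5 (one-to-one), and
categorizes the remaining detections by their best JI: FN if positive,
FP if zero.  True events that no detection overlaps add further FNs.
For non-overlapping event lists — which thresholded runs always are —
greedy matching provably coincides with the exhaustive
max-total-JI assignment (a true event cannot have JI > 0.5 with two
disjoint detections), and the suite verifies agreement with an
exhaustive oracle on 1,000 random instances.  Event PPV is
TP/(TP + FP), sensitivity TP/(TP + FN_total), F1 their harmonic mean.
Counting entirely-missed true events in the recall denominator is an
interpretation (the category rule attaches only to detected events);
omitting them would let a detector score perfectly by predicting one
safe event.

MAPE is the mean over recordings (with ≥ 1 true event) of
|n_detected − n_true| / n_true, in %, re-running full postprocessing at
each threshold.  The count-based operand (rather than duration) matches
the clinical use named for event detection, respiratory-rate
estimation, and is flagged as an interpretation.

## Synthetic generator

The generator emulates the *statistical structure* of the HF_Lung_V1
corpus, not airway acoustics.  Per 15-s recording, 4 breath cycles are
laid on a jittered grid (a 15-s recording should hold at least three
full cycles).  Event durations are log-normal (σ_log = 0.25) truncated
to [0.2, 3] s with means set to the corpus values — I 0.93 s, E 0.96 s,
CAS 0.83 s, DAS 0.89 s; the spread is a free knob, as only means are
published.  Exhalations follow inhalations after a 0.05–0.25 s pause
and are rendered only with probability 0.55 (not every exhalation is
audible; the corpus has ~0.54 E per I).  Each cycle carries one CAS
event with probability 0.4 (class drawn W:S:R ∝ 8457:686:4740) and one
DAS event with probability 0.4, both anchored inside the breath phase.

Rendering: breath phases are 100–1200 Hz (I) / 100–800 Hz (E) band-
limited noise under an attack–decay envelope, exhalations at 0.6×
amplitude; CAS events are a sinusoid with 1–2 harmonics, tone drawn
from class-specific ranges following auscultation convention (rhonchus
100–200 Hz, wheeze 250–700 Hz, stridor 500–900 Hz — chosen to keep
classes separable, not published values); DAS events are trains of
5–20 damped-sinusoid impulses/s, each 15 ms (< 25 ms, the
single-crackle bound).  Background noise at 10 dB SNR by default —
clean enough that a desk-scale model can learn, noisy enough to be
non-trivial — with white, pink, 60-Hz-hum, and ventilator-like
(periodic broadband bursts uncorrelated with labels, a known CAS
false-positive confounder) flavors.  Output is peak-normalized to 0.9
and is a bit-exact function of (config, seed).

What the generator does **not** emulate: real airway acoustics and
disease-specific morphology, recording-hardware transfer functions,
overlapping same-class events, human-labeler noise, and unusual breath
patterns (apnea, double triggering).  Synthetic-recovery results
therefore show that the pipeline is *correct and trainable*, not that
it attains any particular accuracy on real lung sounds.

## Scaled-down study sizes

The full benchmark (9,765 recordings, 12 models × 4 tasks, hundreds of
epochs) is GPU-scale.  The package's own experiments use sizes chosen
to exercise every code path on one CPU core: the synthetic-recovery
test trains the SIMP BiGRU on 200 recordings (180/20 train/val) for 10
epochs at learning rate 10⁻³ and evaluates 50 held-out recordings
(reaching held-out inhalation segment AUC ≈ 0.999 and event F1 = 1.0
after default postprocessing); the end-to-end demo uses 15 recordings
and 2 epochs.  The raised learning rate and epoch cap are scaled-run
settings passed explicitly; package defaults remain the benchmark
protocol values.

## Known limitations

* The CNN front end is a documented stand-in for an underdetermined
  published layout; CNN parameter counts are advisory.
* The numpy training loop is single-threaded BLAS-bound; it is meant
  for desk-scale experiments, not corpus-scale training.
* MFCC filterbank and delta conventions (HTK mel, unnormalized
  triangles, edge replication, c₀ included) are fixed, reasonable
  choices among several the protocol does not pin down; models trained
  on features from other toolchains are not weight-compatible.
* The label TSV dialect stores times at µs precision; round-tripping
  preserves events to ≥ 1 ms as required but is not bit-exact for
  arbitrary floats.
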