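# lungsed

Breath-phase and adventitious-sound event detection in lung-sound
recordings.

Auscultation-based monitoring needs algorithms that do more than say
"this recording contains a wheeze": for respiratory-rate estimation and
therapy monitoring a detector must recover the *start and end time* of
every inhalation (I), exhalation (E), continuous adventitious sound
(CAS — wheeze, stridor, rhonchus, pooled as one class C) and
discontinuous adventitious sound (DAS — crackles) in a recording.
`lungsed` implements a complete benchmark framework for this task on
15-s, 4-kHz mono recordings, for researchers developing or evaluating
respiratory-sound detectors:

* **audio/label I/O** — PCM WAVE in/out, headerless TSV event labels
  (`onset<TAB>offset<TAB>class`), the two truncation protocols used for
  field recordings (15.8-s stethoscope files cropped by 0.8 s; long
  multichannel files cut to their first 15 s), and dataset manifests
  with subject/day grouping keys;
* **features** — per recording, a 938 × 193 matrix: 129-bin
  log-magnitude STFT spectrogram (Hann 256, hop 64, after a zero-phase
  10th-order 80-Hz high-pass), 20 MFCCs + 20 Δ + 20 Δ² (width-9
  regression), and energy sums over 0–250 / 250–500 / 500–1000 /
  0–2000 Hz, each column min–max normalized to [0, 1];
* **detector zoo** — per-frame sequence labelers implemented in numpy
  (no deep-learning framework required): LSTM, GRU, BiLSTM, BiGRU,
  their CNN-fronted variants (output halved to 469 frames), and the
  SIMP bidirectional variants with halved recurrent width.  Training
  uses Adam (lr 10⁻⁴), ×0.2 plateau decay (patience 10), 50-epoch early
  stopping, per-frame binary cross-entropy, and day-grouped k-fold
  splits that never let one acquisition session span two folds;
* **postprocessing** — thresholded frame runs become events; fragments
  separated by < T = 0.5 s whose spectral energy peaks differ by
  < P = 25 Hz are merged (left-to-right, cascading, peaks recomputed);
  bursts shorter than 0.05 s are deleted;
* **evaluation** — segment-level confusion/ROC/AUC and event-level
  matching by Jaccard index (TP iff JI > 0.5; 0 < JI ≤ 0.5 is FN;
  JI = 0 is FP), plus the event-count MAPE-vs-threshold curve;
* **synthetic generator** — seeded, annotated 15-s recordings whose
  event statistics emulate the public HF_Lung_V1 corpus (mean durations
  I 0.93 s, E 0.96 s, CAS 0.83 s, DAS 0.89 s; exhalations audible with
  p ≈ 0.55; crackle impulses < 25 ms), so every stage is testable
  without downloading data.

The eight full model variants reproduce the published trainable-
parameter counts exactly (LSTM 300,609; GRU 227,265; BiLSTM 732,225;
BiGRU 552,769; SIMP BiLSTM 235,073; SIMP BiGRU 178,113); see
`docs/methods.md` for the architecture reading and for the CNN front
end, whose internals are underdetermined and reported as advisory.

**Scope note:** the published full-corpus benchmark numbers (e.g.
BiGRU inhalation event F1 86.2%) require the real 9,765-recording
HF_Lung_V1 database and GPU-scale training of 12 models × 4 tasks.
They are *not* reproducible at desk scale, and this package does not
claim them; it ships the framework, correctness property suites, and a
scaled-down synthetic workflow instead.  Pointing the manifest at a
local copy of the real corpus works unchanged.

## Worked example

Train the SIMP BiGRU inhalation detector on 40 synthetic recordings and
score 10 held-out ones (`examples/03_train_inhalation_detector.py`):

```
model: SIMP BiGRU, 178,113 trainable parameters
epoch    1  train 0.7296  val 0.5659  lr 1.00e-03
...
epoch    5  train 0.4251  val 0.3738  lr 1.00e-03
held-out inhalation segment AUC over 10 recordings: 0.953
```

The AUC is the probability that a frame inside a labeled inhalation
scores above a background frame; 0.95 after five epochs at this tiny
scale means the detector has learned the breath-phase energy envelope.
Postprocessing and event scoring with an oracle score sequence
(`examples/04_postprocess_and_score_events.py`):

```
4 true inhalations; 4 detected events:
  [ 0.056,  1.320] s  energy peak 1000.00 Hz
  ...
TP=4 FP=0 FN=0  PPV=1.00 sensitivity=1.00 F1=1.00
```

Every detected interval overlaps its label with JI ≈ 1, so all four are
true positives.  The other examples cover dataset synthesis and the
feature matrix; the `lungsed` command line exposes the same stages
(`synth`, `featurize`, `train`, `predict`, `postprocess`, `evaluate`,
`run`).

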