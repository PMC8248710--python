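"""Segment- and event-level evaluation.

Two tasks are scored per recording and detection class:

* **Segment classification** — frame-wise comparison of the thresholded
  score sequence against the per-frame targets, giving a TP/TN/FP/FN
  confusion and the usual ratios (accuracy, PPV, sensitivity,
  specificity, F1).  Sweeping the threshold over the pooled frames gives
  the ROC curve and its trapezoidal AUC.
* **Event detection** — detected intervals are matched to ground-truth
  intervals by the Jaccard index (intersection over union of the two
  time spans).  A predicted event is a TP when its JI with a (one-to-one
  matched) ground-truth event exceeds 0.5, an FN when 0 < JI <= 0.5, and
  an FP when JI = 0; a TN event is undefined.  Ground-truth events that
  no prediction overlaps add further FNs to the recall denominator.
  Matching is greedy by descending JI, which for non-overlapping event
  lists coincides with the exhaustive max-JI assignment.

MAPE (mean absolute percentage error) measures the per-recording
*event-count* error after postprocessing, averaged over recordings with
at least one true event, as a function of the detection threshold —
the quantity that matters for respiratory-rate estimation.

Undefined ratios (0/0) are reported as ``None`` and excluded from macro
averages rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn import metrics as sk_metrics

from .models import PredictionSequence
from .postprocess import DetectedEvent, PostprocessConfig, postprocess
from .targets import TargetSequence


@dataclass
class SegmentConfusion:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "SegmentConfusion") -> "SegmentConfusion":
        return SegmentConfusion(self.tp + other.tp, self.tn + other.tn,
                                self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricReport:
    accuracy: float | None = None
    ppv: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    auc: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def segment_confusion(pred_binary: np.ndarray | Sequence[int],
                      truth: TargetSequence | np.ndarray) -> SegmentConfusion:
    """Frame-wise TP/TN/FP/FN counts."""
    p = np.asarray(pred_binary).astype(bool)
    t = (truth.values if isinstance(truth, TargetSequence) else np.asarray(truth)).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: prediction {p.shape}, truth {t.shape}")
    return SegmentConfusion(
        tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)))


def metrics(conf: SegmentConfusion) -> MetricReport:
    """Standard ratios; 0/0 cases are None (excluded from averages)."""
    ppv = _ratio(conf.tp, conf.tp + conf.fp)
    sens = _ratio(conf.tp, conf.tp + conf.fn)
    spec = _ratio(conf.tn, conf.tn + conf.fp)
    acc = _ratio(conf.tp + conf.tn, conf.total)
    f1 = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    elif ppv is not None and sens is not None:
        f1 = 0.0
    return MetricReport(accuracy=acc, ppv=ppv, sensitivity=sens,
                        specificity=spec, f1=f1)


def roc_auc(scores: np.ndarray | Sequence[float],
            truths: np.ndarray | Sequence[int]) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over pooled frames; returns (fpr, tpr, trapezoidal AUC)."""
    y = np.asarray(truths).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise ValueError("scores and truths must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: truth contains a single class")
    fpr, tpr, _ = sk_metrics.roc_curve(y, s)
    return fpr, tpr, float(sk_metrics.auc(fpr, tpr))


def jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Intersection-over-union of two closed time intervals."""
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0.0:
        return 0.0
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union


def _interval(ev) -> tuple[float, float]:
    return (ev.onset_s, ev.offset_s)


@dataclass
class MatchOutcome:
    """Event-level matching result for one recording."""

    tp: int = 0
    fn_pred: int = 0         # predicted events with 0 < JI <= 0.5
    fp: int = 0              # predicted events with JI = 0
    fn_missed: int = 0       # truths overlapped by no prediction
    pred_ji: list[float] = field(default_factory=list)
    pred_category: list[str] = field(default_factory=list)
    truth_matched: list[bool] = field(default_factory=list)

    @property
    def fn_total(self) -> int:
        return self.fn_pred + self.fn_missed

    def __add__(self, other: "MatchOutcome") -> "MatchOutcome":
        return MatchOutcome(
            tp=self.tp + other.tp, fn_pred=self.fn_pred + other.fn_pred,
            fp=self.fp + other.fp, fn_missed=self.fn_missed + other.fn_missed,
            pred_ji=self.pred_ji + other.pred_ji,
            pred_category=self.pred_category + other.pred_category,
            truth_matched=self.truth_matched + other.truth_matched)


def match_events(pred_events: Sequence[DetectedEvent],
                 truth_events: Sequence) -> MatchOutcome:
    """Greedy one-to-one JI matching with the category rule.

    Pairs are considered in descending JI order; a pair with JI > 0.5
    whose two members are both unclaimed becomes a TP.  Every remaining
    predicted event is categorized by its best JI against *any* truth
    (FN if positive, FP if zero), and truths with no overlapping
    prediction count as additional misses.
    """
    preds = [_interval(e) for e in pred_events]
    truths = [_interval(e) for e in truth_events]
    ji = np.zeros((len(preds), len(truths)))
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            ji[i, j] = jaccard(p, t)

    outcome = MatchOutcome()
    pred_used = [False] * len(preds)
    truth_used = [False] * len(truths)
    if ji.size:
        order = np.argsort(ji, axis=None)[::-1]
        for flat in order:
            i, j = divmod(int(flat), len(truths))
            if ji[i, j] <= 0.5:
                break
            if pred_used[i] or truth_used[j]:
                continue
            pred_used[i] = True
            truth_used[j] = True
            outcome.tp += 1

    categories = [""] * len(preds)
    ji_best = ji.max(axis=1) if ji.size else np.zeros(len(preds))
    for i in range(len(preds)):
        if pred_used[i]:
            categories[i] = "TP"
        elif ji_best[i] > 0:
            categories[i] = "FN"
            outcome.fn_pred += 1
        else:
            categories[i] = "FP"
            outcome.fp += 1
    for j in range(len(truths)):
        overlapped = bool(ji[:, j].max() > 0) if ji.size else False
        if not overlapped:
            outcome.fn_missed += 1
    outcome.pred_ji = [float(v) for v in ji_best]
    outcome.pred_category = categories
    outcome.truth_matched = truth_used
    return outcome


def event_f1(outcome: MatchOutcome) -> MetricReport:
    """Event-level PPV = TP/(TP+FP), sensitivity = TP/(TP+FN_total), F1."""
    n_pred = outcome.tp + outcome.fp + outcome.fn_pred
    n_truth = outcome.tp + outcome.fn_total
    if n_pred == 0 and n_truth == 0:
        return MetricReport()
    ppv = _ratio(outcome.tp, outcome.tp + outcome.fp)
    sens = _ratio(outcome.tp, outcome.tp + outcome.fn_total)
    f1 = None
    if ppv is not None and sens is not None:
        f1 = 0.0 if (ppv + sens) == 0 else 2 * ppv * sens / (ppv + sens)
    return MetricReport(ppv=ppv, sensitivity=sens, f1=f1)


def mape_curve(predictions: Sequence[PredictionSequence],
               truth_event_lists: Sequence[Sequence],
               spectrograms: Sequence,
               thresholds: Sequence[float],
               config: PostprocessConfig | None = None) -> np.ndarray:
    """Event-count MAPE (%) per threshold, averaged over recordings.

    For each threshold the full postprocessing chain is re-run; each
    recording with ``n_truth > 0`` contributes
    ``|n_detected - n_truth| / n_truth`` and the mean is reported in %.
    """
    config = config or PostprocessConfig()
    out = np.zeros(len(thresholds))
    for k, thr in enumerate(thresholds):
        cfg = PostprocessConfig(threshold=float(thr),
                                merge_gap_T=config.merge_gap_T,
                                peak_diff_P=config.peak_diff_P,
                                min_duration=config.min_duration)
        errors = []
        for pred, truths, spec in zip(predictions, truth_event_lists, spectrograms):
            n_truth = len(truths)
            if n_truth == 0:
                continue
            detected = postprocess(pred, spec, cfg)
            errors.append(abs(len(detected) - n_truth) / n_truth)
        out[k] = 100.0 * float(np.mean(errors)) if errors else np.nan
    return out


def macro_average(reports: Sequence[MetricReport]) -> MetricReport:
    """Per-recording macro mean, skipping undefined (None) entries."""
    fields = ("accuracy", "ppv", "sensitivity", "specificity", "f1", "auc")
    values = {}
    for name in fields:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        values[name] = float(np.mean(vals)) if vals else None
    return MetricReport(**values)


def plot_roc(fpr: np.ndarray, tpr: np.ndarray, auc_value: float, path: str):
    """Write a ROC curve figure (lazy matplotlib import)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {auc_value:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mape(thresholds: Sequence[float], mape: np.ndarray, path: str):
    """Write a MAPE-vs-threshold figure (lazy matplotlib import)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(thresholds, mape)
    ax.set_xlabel("detection threshold")
    ax.set_ylabel("event-count MAPE (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
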