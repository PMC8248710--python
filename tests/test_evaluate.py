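"""Evaluation: confusions, ratios, ROC/AUC oracle, JI matching, MAPE."""

import numpy as np
import pytest
from scipy import stats

from lungsed import (
    MatchOutcome,
    event_f1,
    jaccard,
    macro_average,
    mape_curve,
    match_events,
    metrics,
    roc_auc,
    segment_confusion,
)
from lungsed.evaluate import SegmentConfusion
from lungsed.postprocess import DetectedEvent


def _iv(onset, offset):
    return DetectedEvent(onset, offset)


class TestSegmentConfusion:
    def test_perfect_agreement(self):
        conf = segment_confusion([1, 1, 0, 0], np.array([1, 1, 0, 0]))
        assert (conf.tp, conf.tn, conf.fp, conf.fn) == (2, 2, 0, 0)

    def test_inverted_prediction(self):
        conf = segment_confusion([0, 0, 1, 1], np.array([1, 1, 0, 0]))
        assert conf.tp == 0 and conf.tn == 0
        assert conf.fp == 2 and conf.fn == 2

    def test_mixed_case(self):
        conf = segment_confusion([1, 0, 1, 0], np.array([1, 1, 0, 0]))
        assert (conf.tp, conf.fn, conf.fp, conf.tn) == (1, 1, 1, 1)

    def test_counts_sum_to_frames(self):
        rng = np.random.default_rng(0)
        p, t = rng.integers(0, 2, 938), rng.integers(0, 2, 938)
        assert segment_confusion(p, t).total == 938

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            segment_confusion([1, 0], np.array([1, 0, 1]))


class TestMetrics:
    def test_standard_formulas(self):
        rep = metrics(SegmentConfusion(tp=8, fp=2, fn=2, tn=8))
        assert rep.ppv == pytest.approx(0.8)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.8)

    def test_all_zero_counts_undefined(self):
        rep = metrics(SegmentConfusion())
        assert rep.accuracy is None and rep.ppv is None
        assert rep.sensitivity is None and rep.specificity is None

    def test_degenerate_positive_only(self):
        rep = metrics(SegmentConfusion(tp=1))
        assert rep.f1 == pytest.approx(1.0)
        assert rep.specificity is None

    def test_macro_average_skips_undefined(self):
        reports = [metrics(SegmentConfusion(tp=1)),
                   metrics(SegmentConfusion(tn=5))]
        avg = macro_average(reports)
        assert avg.f1 == pytest.approx(1.0)      # only one defined F1
        assert avg.specificity == pytest.approx(1.0)


class TestRocAuc:
    def test_perfect_scores_auc_one(self):
        truth = np.array([0, 1, 0, 1, 1])
        _, _, auc = roc_auc(truth.astype(float), truth)
        assert auc == pytest.approx(1.0)

    def test_inverted_scores_auc_zero(self):
        truth = np.array([0, 1, 0, 1, 1])
        _, _, auc = roc_auc(1.0 - truth, truth)
        assert auc == pytest.approx(0.0)

    def test_independent_scores_auc_half(self):
        rng = np.random.default_rng(42)
        scores = rng.random(10_000)
        truth = rng.integers(0, 2, 10_000)
        _, _, auc = roc_auc(scores, truth)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_trapezoidal_auc_equals_rank_statistic(self):
        # closed-form oracle: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos n_neg)
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(20, 400))
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                continue
            scores = np.round(rng.random(n), 2)  # force ties
            ranks = stats.rankdata(scores)
            n_pos, n_neg = truth.sum(), n - truth.sum()
            u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2
            expected = u / (n_pos * n_neg)
            _, _, auc = roc_auc(scores, truth)
            assert auc == pytest.approx(expected, abs=1e-9)


class TestJaccardMatching:
    def test_exact_overlap_is_tp(self):
        out = match_events([_iv(0.0, 1.0)], [_iv(0.0, 1.0)])
        assert out.tp == 1 and out.fp == 0 and out.fn_total == 0
        assert out.pred_category == ["TP"]

    def test_small_overlap_is_fn(self):
        # JI = 0.2 / 1.8 = 0.111...
        out = match_events([_iv(0.0, 1.0)], [_iv(0.8, 1.8)])
        assert out.pred_ji[0] == pytest.approx(0.2 / 1.8)
        assert out.pred_category == ["FN"]
        assert out.tp == 0 and out.fn_total == 1

    def test_no_overlap_is_fp(self):
        out = match_events([_iv(2.0, 3.0)], [_iv(0.0, 1.0)])
        assert out.pred_category == ["FP"]
        assert out.fp == 1
        assert out.fn_missed == 1  # the unmatched truth counts as a miss

    def test_ji_boundary_exactly_half_is_fn(self):
        # pred [0, 1], truth [0, 2]: JI = 0.5, not > 0.5
        out = match_events([_iv(0.0, 1.0)], [_iv(0.0, 2.0)])
        assert out.pred_ji[0] == pytest.approx(0.5)
        assert out.pred_category == ["FN"]

    def test_each_truth_credited_once(self):
        preds = [_iv(0.0, 1.0), _iv(0.05, 1.05)]
        out = match_events(preds, [_iv(0.0, 1.0)])
        assert out.tp == 1
        assert sorted(out.pred_category) == ["FN", "TP"]

    def test_missed_truths_add_fns(self):
        out = match_events([], [_iv(0.0, 1.0), _iv(2.0, 3.0)])
        assert out.fn_missed == 2
        rep = event_f1(out)
        assert rep.sensitivity == 0.0

    def test_agrees_with_exhaustive_max_ji_assignment(self):
        import itertools

        rng = np.random.default_rng(11)

        def brute_force(preds, truths):
            # exhaustive one-to-one assignment maximizing total JI
            # (ties resolved toward more JI > 0.5 pairs), then the
            # per-event category rule
            n, m = len(preds), len(truths)
            ji = np.array([[jaccard((p.onset_s, p.offset_s),
                                    (t.onset_s, t.offset_s))
                            for t in truths] for p in preds]).reshape(n, m)
            best_total, best_tp = -1.0, 0
            if n == 0 or m == 0:
                best_tp = 0
            elif n <= m:
                for perm in itertools.permutations(range(m), n):
                    total = sum(ji[i, perm[i]] for i in range(n))
                    tp = sum(ji[i, perm[i]] > 0.5 for i in range(n))
                    if total > best_total + 1e-12 or \
                            (abs(total - best_total) <= 1e-12 and tp > best_tp):
                        best_total, best_tp = total, tp
            else:
                for perm in itertools.permutations(range(n), m):
                    total = sum(ji[perm[j], j] for j in range(m))
                    tp = sum(ji[perm[j], j] > 0.5 for j in range(m))
                    if total > best_total + 1e-12 or \
                            (abs(total - best_total) <= 1e-12 and tp > best_tp):
                        best_total, best_tp = total, tp
            fp = sum(1 for i in range(n) if m == 0 or ji[i].max() == 0)
            fn_pred = n - best_tp - fp
            fn_missed = sum(1 for j in range(m) if n == 0 or ji[:, j].max() == 0)
            return best_tp, fp, fn_pred + fn_missed

        def random_side(rng, max_events=6):
            n = int(rng.integers(0, max_events + 1))
            events, cursor = [], 0.0
            for s in np.sort(rng.uniform(0, 14, n)):
                onset = max(s, cursor)
                offset = onset + float(rng.uniform(0.1, 1.2))
                if offset > 15:
                    break
                events.append(_iv(onset, offset))
                cursor = offset + 0.01
            return events

        n_checked = 0
        for _ in range(1000):
            preds = random_side(rng)
            truths = random_side(rng)
            got = match_events(preds, truths)
            tp, fp, fn = brute_force(preds, truths)
            assert got.tp == tp
            assert got.fp == fp
            assert got.fn_total == fn
            n_checked += 1
        assert n_checked == 1000


class TestJaccardProperties:
    from hypothesis import given, settings, strategies as st

    interval = st.tuples(st.floats(0.0, 14.0), st.floats(0.01, 3.0)).map(
        lambda p: (p[0], p[0] + p[1]))

    @given(interval, interval)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        ji = jaccard(a, b)
        assert 0.0 <= ji <= 1.0
        assert ji == jaccard(b, a)
        assert jaccard(a, a) == 1.0


class TestEventF1:
    def test_constructed_counts(self):
        out = MatchOutcome(tp=8, fn_pred=1, fp=1, fn_missed=1)
        rep = event_f1(out)
        assert rep.ppv == pytest.approx(8 / 9)
        assert rep.sensitivity == pytest.approx(0.8)

    def test_perfect_detection(self):
        rep = event_f1(MatchOutcome(tp=5))
        assert rep.f1 == pytest.approx(1.0)

    def test_balanced_f1(self):
        # PPV = sens = 0.8 -> F1 = 0.8
        out = MatchOutcome(tp=8, fp=2, fn_missed=2)
        assert event_f1(out).f1 == pytest.approx(0.8)


class TestMapeCurve:
    def _setup(self, scores_list, truth_counts):
        from lungsed import PredictionSequence
        from lungsed.features import BIN_HZ, FRAME_STEP_S, Spectrogram
        preds = [PredictionSequence(scores=s, task="I") for s in scores_list]
        specs = [Spectrogram(values=np.zeros((938, 129)),
                             freq_axis=np.arange(129) * BIN_HZ,
                             time_axis=np.arange(938) * FRAME_STEP_S)
                 for _ in preds]
        truths = [[_iv(i + 0.1, i + 0.9) for i in range(c)]
                  for c in truth_counts]
        return preds, truths, specs

    def test_three_of_four_events_is_25_percent(self):
        scores = np.zeros(938)
        for k in range(3):  # three well-separated long runs
            scores[k * 200:k * 200 + 60] = 1.0
        preds, truths, specs = self._setup([scores], [4])
        mape = mape_curve(preds, truths, specs, thresholds=[0.5])
        assert mape[0] == pytest.approx(25.0)

    def test_threshold_above_all_scores_gives_100_percent(self):
        preds, truths, specs = self._setup([np.full(938, 0.3)], [2])
        mape = mape_curve(preds, truths, specs, thresholds=[0.9])
        assert mape[0] == pytest.approx(100.0)

    def test_recording_order_invariance(self):
        rng = np.random.default_rng(3)
        scores = [np.clip(rng.random(938), 0, 1) for _ in range(3)]
        preds, truths, specs = self._setup(scores, [2, 3, 4])
        fwd = mape_curve(preds, truths, specs, thresholds=[0.4, 0.6])
        rev = mape_curve(preds[::-1], truths[::-1], specs, thresholds=[0.4, 0.6])
        assert np.allclose(fwd, rev)
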