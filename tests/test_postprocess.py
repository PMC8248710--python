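"""Postprocessor: assembly, energy peaks, merge rule, burst removal.

The merge/filter chain is checked against an independent brute-force
realization of the same left-to-right cascading policy (recursive,
list-based) iterated to a fixed point, on randomized small instances.
"""

import numpy as np
import pytest

from lungsed import (
    PredictionSequence,
    Recording,
    energy_peak,
    merge_events,
    postprocess,
    remove_bursts,
    stft_logspec,
    threshold_and_assemble,
)
from lungsed.features import BIN_HZ, FRAME_STEP_S, Spectrogram
from lungsed.postprocess import DetectedEvent, PostprocessConfig, with_peaks


def _flat_spectrogram(n_frames=50, seed=None):
    """Random (or constant) linear-power spectrogram for small instances."""
    rng = np.random.default_rng(seed)
    power = rng.random((n_frames, 129)) if seed is not None else np.ones((n_frames, 129))
    values = 20 * np.log10(np.sqrt(power) + 1e-10)
    return Spectrogram(values=values, freq_axis=np.arange(129) * BIN_HZ,
                       time_axis=np.arange(n_frames) * FRAME_STEP_S)


def _tone_spectrogram(freq_amps, n_frames=938):
    """Spectrogram of a synthetic tone mixture (bin-center frequencies)."""
    mag = np.full((n_frames, 129), 1e-6)
    for freq, amp in freq_amps:
        mag[:, int(round(freq / BIN_HZ))] = amp
    return Spectrogram(values=20 * np.log10(mag + 1e-10),
                       freq_axis=np.arange(129) * BIN_HZ,
                       time_axis=np.arange(n_frames) * FRAME_STEP_S)


class TestAssembly:
    def test_all_subthreshold_gives_no_events(self):
        pred = PredictionSequence(scores=np.full(938, 0.2), task="I")
        assert threshold_and_assemble(pred, 0.5) == []

    def test_run_span_arithmetic(self):
        scores = np.zeros(938)
        scores[100:163] = 0.9  # frames 100..162
        pred = PredictionSequence(scores=scores, task="I")
        (ev,) = threshold_and_assemble(pred, 0.5)
        assert ev.onset_s == pytest.approx(1.592)
        assert ev.offset_s == pytest.approx(2.600)

    def test_single_gap_frame_splits_runs(self):
        scores = np.zeros(938)
        scores[10:20] = 0.9
        scores[21:30] = 0.9
        pred = PredictionSequence(scores=scores, task="I")
        assert len(threshold_and_assemble(pred, 0.5)) == 2


class TestEnergyPeak:
    def test_pure_250hz_tone_peaks_at_250(self, tone_recording):
        spec = stft_logspec(tone_recording)
        assert energy_peak(DetectedEvent(1.0, 2.0), spec) == pytest.approx(250.0)

    def test_all_zero_region_ties_to_lowest_bin(self):
        spec = _flat_spectrogram()
        zero = Spectrogram(values=np.full_like(spec.values, -200.0),
                           freq_axis=spec.freq_axis, time_axis=spec.time_axis)
        assert energy_peak(DetectedEvent(0.1, 0.3), zero) == 0.0

    def test_stronger_tone_wins(self):
        spec = _tone_spectrogram([(250.0, 2.0), (609.375, 1.0)])
        assert energy_peak(DetectedEvent(1.0, 2.0), spec) == pytest.approx(250.0)

    def test_zero_frame_event_rejected(self):
        spec = _flat_spectrogram(n_frames=10)
        with pytest.raises(ValueError, match="no spectrogram frame"):
            energy_peak(DetectedEvent(5.0, 6.0), spec)


class TestMergeRule:
    def test_close_same_peak_events_merge(self):
        spec = _tone_spectrogram([(296.875, 1.0)])  # bin 19, everywhere
        events = [DetectedEvent(1.0, 1.8), DetectedEvent(2.1, 2.9)]
        out = merge_events(events, spec, PostprocessConfig())
        assert len(out) == 1
        assert out[0].onset_s == pytest.approx(1.0)
        assert out[0].offset_s == pytest.approx(2.9)

    def test_gap_at_least_T_not_merged(self):
        spec = _tone_spectrogram([(296.875, 1.0)])
        events = [DetectedEvent(1.0, 1.8), DetectedEvent(2.4, 3.0)]  # gap 0.6
        assert len(merge_events(events, spec, PostprocessConfig())) == 2

    def test_peak_difference_at_least_P_not_merged(self):
        # peaks 100 Hz vs 400 Hz (difference 300 >= 25), gap 0.3 < 0.5
        spec_a = _tone_spectrogram([(100.0, 1.0)])
        spec_b = _tone_spectrogram([(400.0, 1.0)])
        events = [
            DetectedEvent(1.0, 1.8, peak_freq_hz=energy_peak(DetectedEvent(1.0, 1.8), spec_a)),
            DetectedEvent(2.1, 2.9, peak_freq_hz=energy_peak(DetectedEvent(2.1, 2.9), spec_b)),
        ]
        out = merge_events(events, _flat_spectrogram(938), PostprocessConfig())
        assert len(out) == 2

    def test_merging_never_shrinks_covered_time(self):
        rng = np.random.default_rng(5)
        spec = _flat_spectrogram(n_frames=200, seed=5)
        events = _random_events(rng, 200)
        out = merge_events(events, spec, PostprocessConfig())
        assert _covered(out) >= _covered(events) - 1e-9


class TestBurstRemoval:
    @pytest.mark.parametrize("duration,kept", [
        (0.04, False),   # shorter than 0.05 s -> deleted
        (0.06, True),
        (0.05, True),    # boundary: "shorter than" is strict
    ])
    def test_duration_rule(self, duration, kept):
        events = [DetectedEvent(1.0, 1.0 + duration)]
        out = remove_bursts(events, PostprocessConfig())
        assert (len(out) == 1) == kept

    def test_never_increases_event_count(self):
        rng = np.random.default_rng(6)
        events = _random_events(rng, 100)
        assert len(remove_bursts(events, PostprocessConfig())) <= len(events)


def _random_events(rng, n_frames):
    mask = rng.random(n_frames) < 0.35
    events = []
    i = 0
    while i < n_frames:
        if mask[i]:
            j = i
            while j + 1 < n_frames and mask[j + 1]:
                j += 1
            events.append(DetectedEvent(max(0.0, i * FRAME_STEP_S - 0.008),
                                        j * FRAME_STEP_S + 0.008))
            i = j + 1
        else:
            i += 1
    return events


def _covered(events):
    return sum(e.duration_s for e in events)


def _oracle_chain(events, spec, cfg):
    """Independent brute force: recursive left-to-right cascade, iterated
    to a fixed point, then burst deletion."""

    def mergeable(a, b):
        return (b.onset_s - a.offset_s < cfg.merge_gap_T
                and abs(b.peak_freq_hz - a.peak_freq_hz) < cfg.peak_diff_P)

    def one_pass(evs):
        if len(evs) < 2:
            return list(evs)
        a, b = evs[0], evs[1]
        if mergeable(a, b):
            merged = DetectedEvent(a.onset_s, max(a.offset_s, b.offset_s))
            merged = DetectedEvent(merged.onset_s, merged.offset_s,
                                   energy_peak(merged, spec))
            return one_pass([merged] + list(evs[2:]))
        return [a] + one_pass(evs[1:])

    evs = with_peaks(sorted(events, key=lambda e: e.onset_s), spec)
    while True:
        nxt = one_pass(evs)
        if len(nxt) == len(evs):
            break
        evs = nxt
    return [e for e in evs if e.duration_s >= cfg.min_duration]


class TestOracleEquivalence:
    def test_matches_brute_force_on_1000_random_instances(self):
        rng = np.random.default_rng(2025)
        n_nonempty = 0
        for _ in range(1000):
            n_frames = int(rng.integers(10, 50))
            spec = _flat_spectrogram(n_frames=n_frames,
                                     seed=int(rng.integers(0, 2**31)))
            events = _random_events(rng, n_frames)
            if not events:
                continue
            n_nonempty += 1
            cfg = PostprocessConfig(
                merge_gap_T=float(rng.uniform(0.01, 0.3)),
                peak_diff_P=float(rng.uniform(5.0, 800.0)),
                min_duration=float(rng.uniform(0.0, 0.1)))
            got = merge_events(events, spec, cfg)
            got = remove_bursts(got, cfg)
            want = _oracle_chain(events, spec, cfg)
            assert [(round(e.onset_s, 9), round(e.offset_s, 9)) for e in got] == \
                [(round(e.onset_s, 9), round(e.offset_s, 9)) for e in want]
        assert n_nonempty >= 900


class TestChainProperties:
    def test_identity_with_zero_thresholds(self):
        rng = np.random.default_rng(8)
        spec = _flat_spectrogram(n_frames=100, seed=8)
        events = with_peaks(_random_events(rng, 100), spec)
        cfg = PostprocessConfig(merge_gap_T=0.0, peak_diff_P=0.0, min_duration=0.0)
        out = remove_bursts(merge_events(events, spec, cfg), cfg)
        assert [(e.onset_s, e.offset_s) for e in out] == \
            [(e.onset_s, e.offset_s) for e in events]

    def test_merge_is_idempotent(self):
        # the merged list is a fixed point: re-merging changes nothing
        rng = np.random.default_rng(9)
        for trial in range(50):
            spec = _flat_spectrogram(n_frames=80, seed=trial)
            events = _random_events(rng, 80)
            if not events:
                continue
            cfg = PostprocessConfig(merge_gap_T=0.15, peak_diff_P=300.0)
            once = merge_events(events, spec, cfg)
            twice = merge_events(once, spec, cfg)
            assert [(e.onset_s, e.offset_s) for e in once] == \
                [(e.onset_s, e.offset_s) for e in twice]

    def test_burst_removal_is_idempotent(self):
        rng = np.random.default_rng(10)
        events = _random_events(rng, 100)
        cfg = PostprocessConfig(min_duration=0.05)
        once = remove_bursts(events, cfg)
        assert remove_bursts(once, cfg) == once

    def test_chain_idempotent_when_nothing_deleted(self):
        # deleting a burst can create new sub-T adjacency between its
        # neighbours, so chain idempotence is only guaranteed when burst
        # removal is a no-op
        rng = np.random.default_rng(12)
        for trial in range(30):
            spec = _flat_spectrogram(n_frames=80, seed=100 + trial)
            events = _random_events(rng, 80)
            if not events:
                continue
            cfg = PostprocessConfig(merge_gap_T=0.15, peak_diff_P=300.0,
                                    min_duration=0.0)
            once = remove_bursts(merge_events(events, spec, cfg), cfg)
            twice = remove_bursts(merge_events(once, spec, cfg), cfg)
            assert [(e.onset_s, e.offset_s) for e in once] == \
                [(e.onset_s, e.offset_s) for e in twice]

    def test_full_chain_on_clean_scores(self, synth_features):
        features, spec, labels = synth_features
        from lungsed import events_to_frames
        target = events_to_frames(labels, "I")
        pred = PredictionSequence(scores=target.values.astype(float), task="I")
        events = postprocess(pred, spec)
        n_truth = sum(1 for e in labels if e.label_class == "I")
        assert 1 <= len(events) <= n_truth
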