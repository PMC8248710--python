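"""Event postprocessing: threshold, assemble, merge, delete bursts.

A thresholded score sequence is first assembled into maximal runs of
positive frames; each run becomes a detected event spanning from the
first frame's center minus half a hop to the last frame's center plus
half a hop.  Because breathing has a characteristic rhythm, a detector
sometimes splits one physiological event into two fragments separated
by a short dip: two consecutive events are therefore merged when the
gap between them is shorter than ``merge_gap_T`` (0.5 s) *and* their
spectral energy peaks differ by less than ``peak_diff_P`` (25 Hz) —
i.e. they look like the same sound.  Scanning is left-to-right and a
merged event (with recomputed peak) may merge again with its successor.
Finally, isolated bursts shorter than ``min_duration`` (0.05 s,
strictly) are deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .features import Spectrogram
from .models import PredictionSequence


@dataclass(frozen=True)
class DetectedEvent:
    """A detected time interval with its spectral energy-peak frequency."""

    onset_s: float
    offset_s: float
    peak_freq_hz: float | None = None

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError("event must satisfy onset < offset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class PostprocessConfig:
    threshold: float = 0.5
    merge_gap_T: float = 0.5       # s
    peak_diff_P: float = 25.0      # Hz
    min_duration: float = 0.05     # s

    def validate(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        for name in ("merge_gap_T", "peak_diff_P", "min_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def threshold_and_assemble(pred: PredictionSequence,
                           threshold: float) -> list[DetectedEvent]:
    """Maximal runs of frames with score >= threshold become events."""
    mask = np.asarray(pred.scores) >= threshold
    if not mask.any():
        return []
    times = pred.frame_times
    hop = float(times[1] - times[0]) if len(times) > 1 else 0.016
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(np.int8), [0]])))
    events = []
    for a, b in zip(edges[::2], edges[1::2] - 1):
        onset = max(0.0, times[a] - hop / 2)
        offset = times[b] + hop / 2
        events.append(DetectedEvent(onset, offset))
    return events


def energy_peak(event: DetectedEvent, spec: Spectrogram) -> float:
    """Bin-center frequency maximizing mean spectral energy over the event.

    Uses the pre-normalization linear power spectrogram; ties break to
    the lowest bin (so an all-zero region reports 0 Hz).
    """
    mask = (spec.time_axis >= event.onset_s) & (spec.time_axis <= event.offset_s)
    if not mask.any():
        raise ValueError(
            f"event [{event.onset_s}, {event.offset_s}] overlaps no spectrogram frame")
    mean_power = spec.linear_power[mask].mean(axis=0)
    return float(spec.freq_axis[int(np.argmax(mean_power))])


def with_peaks(events: list[DetectedEvent],
               spec: Spectrogram) -> list[DetectedEvent]:
    return [replace(ev, peak_freq_hz=energy_peak(ev, spec)) for ev in events]


def merge_events(events: list[DetectedEvent], spec: Spectrogram,
                 config: PostprocessConfig) -> list[DetectedEvent]:
    """Left-to-right cascading merge of close, spectrally similar events.

    A pair is merged when the inter-event gap is strictly below
    ``merge_gap_T`` and the absolute peak difference strictly below
    ``peak_diff_P``; the merged span gets a recomputed peak and may
    merge again with the next event.
    """
    config.validate()
    if not events:
        return []
    events = sorted(events, key=lambda e: (e.onset_s, e.offset_s))
    if any(ev.peak_freq_hz is None for ev in events):
        events = with_peaks(events, spec)
    # a merged event's recomputed peak can unlock a previously unmergeable
    # neighbour, so the pass repeats until the list is stable (this is what
    # makes merge -> burst-removal idempotent)
    while True:
        out: list[DetectedEvent] = [events[0]]
        for nxt in events[1:]:
            cur = out[-1]
            gap = nxt.onset_s - cur.offset_s
            if gap < config.merge_gap_T and \
                    abs(nxt.peak_freq_hz - cur.peak_freq_hz) < config.peak_diff_P:
                merged = DetectedEvent(cur.onset_s, max(cur.offset_s, nxt.offset_s))
                merged = replace(merged, peak_freq_hz=energy_peak(merged, spec))
                out[-1] = merged
            else:
                out.append(nxt)
        if len(out) == len(events):
            return out
        events = out


def remove_bursts(events: list[DetectedEvent],
                  config: PostprocessConfig) -> list[DetectedEvent]:
    """Delete events strictly shorter than ``min_duration`` (0.05 s)."""
    config.validate()
    return [ev for ev in events if not ev.duration_s < config.min_duration]


def postprocess(pred: PredictionSequence, spec: Spectrogram,
                config: PostprocessConfig | None = None) -> list[DetectedEvent]:
    """Full chain: threshold -> assemble -> peaks -> merge -> burst removal."""
    config = config or PostprocessConfig()
    config.validate()
    events = threshold_and_assemble(pred, config.threshold)
    events = with_peaks(events, spec)
    events = merge_events(events, spec, config)
    return remove_bursts(events, config)


def write_events(events: list[DetectedEvent], path: str | Path) -> Path:
    """TSV dialect of the label files plus a peak-frequency column."""
    path = Path(path)
    with open(path, "w") as fh:
        for ev in events:
            peak = "" if ev.peak_freq_hz is None else f"{ev.peak_freq_hz:.3f}"
            fh.write(f"{ev.onset_s:.6f}\t{ev.offset_s:.6f}\t{peak}\n")
    return path
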