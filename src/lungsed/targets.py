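"""Per-frame binary target sequences for the four detection tasks.

A recording's 938 STFT frames are labeled per task: frame ``i`` is
positive iff its center time ``i * 0.016 s`` falls inside any
ground-truth event of the task's class(es).  The continuous
adventitious task (CAS) pools wheeze, stridor and rhonchus labels.
CNN-fronted models emit 469 half-rate frames; their targets are built
by pairwise max-pooling so that a short event present in either
constituent frame survives the 2x time reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import EventLabel
from .features import FRAME_STEP_S, N_FRAMES

TASKS = ("I", "E", "CAS", "DAS")

#: label classes pooled per task
TASK_CLASSES = {
    "I": ("I",),
    "E": ("E",),
    "CAS": ("W", "S", "R"),
    "DAS": ("D",),
}


def frame_centers(n_frames: int = N_FRAMES,
                  step_s: float = FRAME_STEP_S) -> np.ndarray:
    return np.arange(n_frames) * step_s


@dataclass
class TargetSequence:
    """Binary per-frame labels for one task, with frame center times."""

    values: np.ndarray
    task: str
    frame_times: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("target values must be binary")
        if self.frame_times is None:
            # 938-length targets step 0.016 s; 469-length pooled targets 0.032 s
            factor = N_FRAMES / len(self.values)
            self.frame_times = np.arange(len(self.values)) * FRAME_STEP_S * factor
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frame_times) != len(self.values):
            raise ValueError("frame_times length mismatch")

    def __len__(self) -> int:
        return len(self.values)


def events_to_frames(labels: list[EventLabel], task: str,
                     n_frames: int = N_FRAMES) -> TargetSequence:
    """Rasterize events of ``task`` onto the frame grid.

    Membership is by frame-center inclusion in the closed interval
    [onset, offset]; overlapping events union together.
    """
    if task not in TASK_CLASSES:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    centers = frame_centers(n_frames)
    values = np.zeros(n_frames, dtype=np.int8)
    wanted = TASK_CLASSES[task]
    for ev in labels:
        if ev.label_class in wanted:
            values |= ((centers >= ev.onset_s) & (centers <= ev.offset_s)).astype(np.int8)
    return TargetSequence(values=values, task=task, frame_times=centers)


def downsample_targets(seq: TargetSequence) -> TargetSequence:
    """Halve a target sequence by pairwise max (positive if either frame is)."""
    n = len(seq)
    if n % 2 != 0:
        raise ValueError(f"cannot downsample odd-length sequence ({n} frames)")
    pairs = seq.values.reshape(-1, 2)
    values = pairs.max(axis=1)
    # half-rate frame centered between its two constituent frames
    times = seq.frame_times.reshape(-1, 2).mean(axis=1)
    return TargetSequence(values=values, task=seq.task, frame_times=times)


def frames_to_intervals(values: np.ndarray,
                        frame_times: np.ndarray) -> list[tuple[float, float]]:
    """Assemble maximal positive runs back into [onset, offset] intervals.

    Each frame contributes the half-open span ``center +/- hop/2``,
    clamped to non-negative onset times.
    """
    values = np.asarray(values).astype(bool)
    if not values.any():
        return []
    hop = float(frame_times[1] - frame_times[0]) if len(frame_times) > 1 else FRAME_STEP_S
    edges = np.flatnonzero(np.diff(np.concatenate([[0], values.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2] - 1
    return [(max(0.0, frame_times[a] - hop / 2), frame_times[b] + hop / 2)
            for a, b in zip(starts, ends)]
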