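"""WAVE and event-label I/O plus the recording truncation protocol.

All pipeline audio is mono PCM WAVE at 4 kHz / 16 bit.  A standard
recording is exactly 15 s (60,000 samples).  Two acquisition protocols
produce longer files that are cut down to the standard duration:

* electronic-stethoscope files of 15.8 s, whose final 0.8 s is cropped;
* multichannel-recorder files of >= 15 s (nominally 2 min), of which only
  the first 15 s is kept.

Event labels are stored as headerless tab-separated text: one event per
line, ``onset_s<TAB>offset_s<TAB>class``, with class tokens I, E, W, S,
R, D.  The pooled continuous-adventitious class C is never stored; it is
derived downstream as the union of W, S and R.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

SAMPLE_RATE = 4000
STANDARD_SECONDS = 15.0
STANDARD_SAMPLES = 60000
LITTMANN_SAMPLES = 63200  # 15.8 s at 4 kHz
INT16_SCALE = 32768.0

LABEL_CLASSES = ("I", "E", "W", "S", "R", "D")


@dataclass
class Recording:
    """A mono lung-sound recording with normalized float samples in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int = SAMPLE_RATE
    id: str = ""
    source: str = "steth"  # one of {"steth", "trunc", "synth"}

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(
                f"channel count: expected mono (1-D) samples, got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class EventLabel:
    """A labeled sound event: time interval in seconds plus a class token."""

    onset_s: float
    offset_s: float
    label_class: str

    def __post_init__(self) -> None:
        if self.label_class not in LABEL_CLASSES:
            raise ValueError(
                f"unknown class {self.label_class!r}; expected one of {LABEL_CLASSES}"
            )
        if not self.onset_s < self.offset_s:
            raise ValueError(
                f"event must satisfy onset < offset, got [{self.onset_s}, {self.offset_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def read_wav(path: str | Path, expected_rate: int = SAMPLE_RATE) -> Recording:
    """Read a mono 16-bit PCM WAVE file into a :class:`Recording`.

    Integer samples are mapped to [-1, 1) by the symmetric full-scale
    divisor 32768.  Files with the wrong channel count or sampling rate
    are rejected; there is no silent resampling.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"channel count: {path.name} has {data.shape[1]} channels, expected mono"
        )
    if rate != expected_rate:
        raise ValueError(
            f"sampling rate: {path.name} is {rate} Hz, expected {expected_rate} Hz"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / INT16_SCALE
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"sample format: unsupported dtype {data.dtype} in {path.name}")
    return Recording(samples=samples, sample_rate=rate, id=path.stem)


def write_wav(rec: Recording, path: str | Path) -> Path:
    """Write a recording as mono 16-bit PCM WAVE (clipping at full scale)."""
    path = Path(path)
    clipped = np.clip(rec.samples, -1.0, 32767.0 / INT16_SCALE)
    ints = np.round(clipped * INT16_SCALE).astype(np.int16)
    wavfile.write(path, rec.sample_rate, ints)
    return path


def truncate_littmann(rec: Recording) -> Recording:
    """Crop the final 0.8 s from a 15.8-s stethoscope recording.

    Duration is validated by sample count (63,200 at 4 kHz), not header
    metadata; anything else is rejected.
    """
    if rec.n_samples != LITTMANN_SAMPLES:
        raise ValueError(
            f"unexpected duration: got {rec.n_samples} samples, "
            f"expected {LITTMANN_SAMPLES} (15.8 s at {rec.sample_rate} Hz)"
        )
    return Recording(
        samples=rec.samples[:STANDARD_SAMPLES].copy(),
        sample_rate=rec.sample_rate,
        id=rec.id,
        source=rec.source,
    )


def truncate_hftype1(rec: Recording) -> Recording:
    """Keep only the first 15 s of a long multichannel-recorder signal."""
    if rec.n_samples < STANDARD_SAMPLES:
        raise ValueError(
            f"too short: got {rec.n_samples} samples, need at least {STANDARD_SAMPLES}"
        )
    return Recording(
        samples=rec.samples[:STANDARD_SAMPLES].copy(),
        sample_rate=rec.sample_rate,
        id=rec.id,
        source=rec.source,
    )


def read_labels(path: str | Path) -> list[EventLabel]:
    """Read a headerless TSV label file; events are returned sorted by onset.

    Raises ``ValueError`` with the offending line number on malformed
    rows (bad field count, non-numeric times, offset <= onset, unknown
    class token).  Overlapping same-class events are permitted.
    """
    path = Path(path)
    events: list[EventLabel] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            try:
                onset, offset = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric time field") from exc
            try:
                events.append(EventLabel(onset, offset, parts[2].strip()))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
    events.sort(key=lambda e: (e.onset_s, e.offset_s, e.label_class))
    return events


def write_labels(events: Iterable[EventLabel], path: str | Path) -> Path:
    """Write events as headerless TSV with millisecond-or-better precision."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for ev in events:
            fh.write(f"{ev.onset_s:.6f}\t{ev.offset_s:.6f}\t{ev.label_class}\n")
    return path


@dataclass
class Manifest:
    """Dataset manifest: one row per recording with a leakage-grouping key.

    The ``group`` column plays the role of the subject/day key used to
    keep all recordings from one acquisition session inside a single
    cross-validation fold.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["id", "wav_path", "label_path", "group", "duration_s"]))

    COLUMNS = ("id", "wav_path", "label_path", "group", "duration_s")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_duration_min(self) -> float:
        return float(self.frame["duration_s"].sum()) / 60.0

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "Manifest":
        return cls(frame=pd.read_csv(path))

    @classmethod
    def build(cls, rows: Sequence[dict]) -> "Manifest":
        return cls(frame=pd.DataFrame(list(rows), columns=list(cls.COLUMNS)))
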