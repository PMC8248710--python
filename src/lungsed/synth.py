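"""Synthetic annotated lung-sound generator.

Produces 15-s, 4-kHz mono recordings whose event statistics follow the
published corpus statistics of the HF_Lung_V1 database: inhalations with
mean duration 0.93 s, exhalations 0.96 s (audible with probability
~0.55), continuous adventitious sounds (CAS: wheeze/stridor/rhonchus)
with mean 0.83 s rendered as tonal components, and discontinuous
adventitious sounds (DAS: crackles) with mean 0.89 s rendered as trains
of <25 ms damped impulses.  Background noise is added at a configurable
SNR and may be white, pink, 60-Hz hum, or ventilator-like periodic
bursts (a known false-positive confounder for CAS detectors).

Event durations are drawn from a log-normal distribution truncated to
[0.2 s, 3 s] and parameterized by the configured mean: positive,
right-skewed, and plausible for breath sounds.  Class-specific tone
ranges follow standard auscultation definitions (rhonchus low-pitched,
<= 200 Hz; stridor high-pitched, >= 500 Hz; wheeze in between).

Everything is a pure function of ``(config, seed)``: the same seed gives
bit-identical samples and labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml
from scipy import signal as sp_signal

from .audio_io import (
    EventLabel,
    Manifest,
    Recording,
    SAMPLE_RATE,
    STANDARD_SECONDS,
    write_labels,
    write_wav,
)

#: relative class frequencies of wheeze/stridor/rhonchus in the corpus
#: (8457 : 686 : 4740 labels)
CAS_CLASS_WEIGHTS = {"W": 8457, "S": 686, "R": 4740}

#: tone ranges (Hz) per CAS class, from auscultation convention
CAS_TONE_RANGES = {"W": (250.0, 700.0), "S": (500.0, 900.0), "R": (100.0, 200.0)}


@dataclass
class SynthConfig:
    """Generator parameters; defaults encode the emulated corpus statistics."""

    seed: int = 0
    n_cycles: int = 4                  # breath cycles per 15-s recording
    mean_i_dur: float = 0.93           # s, mean inhalation duration
    mean_e_dur: float = 0.96           # s, mean exhalation duration
    p_exhalation_audible: float = 0.55
    p_cas: float = 0.4                 # per-cycle probability of one CAS event
    cas_class_weights: dict = field(default_factory=lambda: dict(CAS_CLASS_WEIGHTS))
    mean_cas_dur: float = 0.83
    p_das: float = 0.4                 # per-cycle probability of one DAS event
    mean_das_dur: float = 0.89
    crackle_impulse_ms: float = 15.0   # single-crackle impulse length, < 25 ms
    snr_db: float = 10.0
    noise_kind: str = "white"          # {white, pink, hum60, ventilator}
    dur_sigma: float = 0.25            # log-std of the truncated log-normal
    dur_bounds: tuple = (0.2, 3.0)

    def validate(self) -> None:
        for name in ("mean_i_dur", "mean_e_dur", "mean_cas_dur", "mean_das_dur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.p_exhalation_audible <= 1:
            raise ValueError("p_exhalation_audible must be a probability")
        if self.crackle_impulse_ms >= 25.0:
            raise ValueError("crackle_impulse_ms must stay below 25 ms")
        if self.noise_kind not in ("white", "pink", "hum60", "ventilator"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        # every cycle must fit an inhalation + (possibly) an exhalation
        if self.n_cycles * (self.mean_i_dur + self.mean_e_dur) > STANDARD_SECONDS:
            raise ValueError(
                "overcrowded: n_cycles x mean breath durations exceed the 15-s recording"
            )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "dur_bounds" in data:
            data["dur_bounds"] = tuple(data["dur_bounds"])
        return cls(**data)


def _truncated_lognormal(rng: np.random.Generator, mean: float, sigma: float,
                         bounds: tuple[float, float]) -> float:
    """Log-normal sample with expectation ``mean``, rejection-truncated."""
    mu = np.log(mean) - 0.5 * sigma**2
    for _ in range(1000):
        x = float(rng.lognormal(mu, sigma))
        if bounds[0] <= x <= bounds[1]:
            return x
    return float(np.clip(mean, *bounds))


def sample_schedule(config: SynthConfig,
                    rng: np.random.Generator) -> list[EventLabel]:
    """Draw the event timeline (no audio) for one 15-s recording.

    Cycles are laid out on a jittered grid; each carries an inhalation,
    an exhalation with probability ``p_exhalation_audible`` after a short
    pause, and optionally one CAS and/or one DAS event anchored inside
    the breath phases (adventitious sounds are produced by breathing, so
    they overlap the phases they decorate).
    """
    config.validate()
    period = STANDARD_SECONDS / config.n_cycles
    events: list[EventLabel] = []
    for k in range(config.n_cycles):
        start = k * period + float(rng.uniform(0.0, 0.12 * period))
        i_dur = _truncated_lognormal(rng, config.mean_i_dur, config.dur_sigma,
                                     config.dur_bounds)
        i_end = min(start + i_dur, STANDARD_SECONDS)
        if i_end - start < config.dur_bounds[0]:
            continue
        events.append(EventLabel(round(start, 6), round(i_end, 6), "I"))

        e_start = i_end + float(rng.uniform(0.05, 0.25))
        if rng.random() < config.p_exhalation_audible:
            e_dur = _truncated_lognormal(rng, config.mean_e_dur, config.dur_sigma,
                                         config.dur_bounds)
            e_end = min(e_start + e_dur, (k + 1) * period)
            if e_end - e_start >= config.dur_bounds[0] and e_end <= STANDARD_SECONDS:
                events.append(EventLabel(round(e_start, 6), round(e_end, 6), "E"))

        if rng.random() < config.p_cas:
            classes = list(config.cas_class_weights)
            weights = np.array([config.cas_class_weights[c] for c in classes], float)
            cls = classes[int(rng.choice(len(classes), p=weights / weights.sum()))]
            c_dur = _truncated_lognormal(rng, config.mean_cas_dur, config.dur_sigma,
                                         config.dur_bounds)
            c_start = start + float(rng.uniform(0.0, max(1e-3, (i_end - start) * 0.3)))
            c_end = min(c_start + c_dur, STANDARD_SECONDS)
            if c_end - c_start >= config.dur_bounds[0]:
                events.append(EventLabel(round(c_start, 6), round(c_end, 6), cls))

        if rng.random() < config.p_das:
            d_dur = _truncated_lognormal(rng, config.mean_das_dur, config.dur_sigma,
                                         config.dur_bounds)
            d_start = start + float(rng.uniform(0.0, max(1e-3, (i_end - start) * 0.5)))
            d_end = min(d_start + d_dur, STANDARD_SECONDS)
            if d_end - d_start >= config.dur_bounds[0]:
                events.append(EventLabel(round(d_start, 6), round(d_end, 6), "D"))

    events.sort(key=lambda e: (e.onset_s, e.offset_s, e.label_class))
    return events


def _attack_decay_envelope(n: int, attack_frac: float = 0.3) -> np.ndarray:
    """Piecewise-linear attack/decay amplitude envelope of length ``n``."""
    n_attack = max(1, int(n * attack_frac))
    env = np.ones(n)
    env[:n_attack] = np.linspace(0.0, 1.0, n_attack)
    env[n_attack:] = np.linspace(1.0, 0.05, n - n_attack)
    return env

_BREATH_SOS = {}


def _breath_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                  fs: int) -> np.ndarray:
    """Band-limited noise burst used for breath-phase sounds."""
    key = (band, fs)
    if key not in _BREATH_SOS:
        _BREATH_SOS[key] = sp_signal.butter(4, band, btype="bandpass", fs=fs,
                                            output="sos")
    x = rng.standard_normal(n)
    x = sp_signal.sosfilt(_BREATH_SOS[key], x)
    rms = np.sqrt(np.mean(x**2)) or 1.0
    return x / rms


def _render_cas(rng: np.random.Generator, n: int, f0: float, fs: int) -> np.ndarray:
    """Tonal CAS component: fundamental plus 1-2 weaker harmonics."""
    t = np.arange(n) / fs
    phase = float(rng.uniform(0, 2 * np.pi))
    x = np.sin(2 * np.pi * f0 * t + phase)
    x += 0.5 * np.sin(2 * np.pi * 2 * f0 * t + phase * 1.7)
    if 3 * f0 < fs / 2:
        x += 0.25 * np.sin(2 * np.pi * 3 * f0 * t + phase * 2.3)
    window = np.hanning(n) if n > 2 else np.ones(n)
    return x * window


def _render_das(rng: np.random.Generator, n: int, impulse_ms: float,
                fs: int) -> np.ndarray:
    """Crackle train: damped-sinusoid impulses, each shorter than ``impulse_ms``."""
    out = np.zeros(n)
    rate = float(rng.uniform(5.0, 20.0))  # impulses per second
    n_imp = max(2, int(round(rate * n / fs)))
    imp_len = int(impulse_ms / 1000.0 * fs)
    t = np.arange(imp_len) / fs
    for _ in range(n_imp):
        pos = int(rng.integers(0, max(1, n - imp_len)))
        f = float(rng.uniform(200.0, 1200.0))
        # decay constant chosen so the tail is < 1% by the impulse end
        tau = impulse_ms / 1000.0 / 5.0
        imp = np.exp(-t / tau) * np.sin(2 * np.pi * f * t)
        out[pos:pos + imp_len] += imp
    return out


def _background(rng: np.random.Generator, n: int, kind: str, fs: int) -> np.ndarray:
    """Unit-RMS background noise of the requested flavor."""
    if kind == "white":
        x = rng.standard_normal(n)
    elif kind == "pink":
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        spec /= np.sqrt(np.maximum(freqs, 1.0))
        x = np.fft.irfft(spec, n)
    elif kind == "hum60":
        t = np.arange(n) / fs
        x = (np.sin(2 * np.pi * 60 * t) + 0.3 * np.sin(2 * np.pi * 180 * t)
             + 0.1 * rng.standard_normal(n))
    elif kind == "ventilator":
        # periodic broadband bursts uncorrelated with the labels
        x = 0.1 * rng.standard_normal(n)
        period = int(3.1 * fs)
        burst_len = int(0.4 * fs)
        burst_env = np.hanning(burst_len)
        start = int(rng.integers(0, period))
        for pos in range(start, n - burst_len, period):
            x[pos:pos + burst_len] += burst_env * rng.standard_normal(burst_len)
    else:  # pragma: no cover - validated upstream
        raise ValueError(kind)
    rms = np.sqrt(np.mean(x**2)) or 1.0
    return x / rms


def generate_recording(config: SynthConfig, *, return_details: bool = False):
    """Generate one annotated synthetic recording.

    Returns ``(Recording, labels)``; with ``return_details=True`` a third
    element carries per-event rendering metadata (e.g. CAS tone
    frequencies) for verification.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = SAMPLE_RATE
    n_total = int(STANDARD_SECONDS * fs)
    labels = sample_schedule(config, rng)

    clean = np.zeros(n_total)
    details: list[dict] = []
    for ev in labels:
        a = int(round(ev.onset_s * fs))
        b = min(int(round(ev.offset_s * fs)), n_total)
        n = b - a
        if n <= 8:
            continue
        info: dict = {"event": ev}
        if ev.label_class == "I":
            x = _breath_noise(rng, n, (100.0, 1200.0), fs)
            x *= _attack_decay_envelope(n) * 1.0
        elif ev.label_class == "E":
            x = _breath_noise(rng, n, (100.0, 800.0), fs)
            x *= _attack_decay_envelope(n, attack_frac=0.2) * 0.6
        elif ev.label_class in ("W", "S", "R"):
            lo, hi = CAS_TONE_RANGES[ev.label_class]
            f0 = float(rng.uniform(lo, hi))
            info["tone_hz"] = f0
            x = 0.7 * _render_cas(rng, n, f0, fs)
        else:  # "D"
            x = 0.9 * _render_das(rng, n, config.crackle_impulse_ms, fs)
        clean[a:b] += x
        details.append(info)

    sig_rms = np.sqrt(np.mean(clean**2))
    if sig_rms == 0:
        sig_rms = 1.0
    noise = _background(rng, n_total, config.noise_kind, fs)
    noise_rms = sig_rms * 10.0 ** (-config.snr_db / 20.0)
    samples = clean + noise * noise_rms

    peak = np.max(np.abs(samples))
    if peak > 0:
        samples *= 0.9 / peak

    rec = Recording(samples=samples, sample_rate=fs,
                    id=f"synth_{config.seed:08d}", source="synth")
    if return_details:
        return rec, labels, details
    return rec, labels


def _spawned_configs(config: SynthConfig, n: int) -> Iterator[SynthConfig]:
    """Derive ``n`` child configs with independent, reproducible seeds."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n) % (2**31)
    for s in seeds:
        yield replace(config, seed=int(s))


def generate_dataset(n: int, config: SynthConfig, out_dir: str | Path, *,
                     recordings_per_group: int = 10,
                     overwrite: bool = False) -> Manifest:
    """Write ``n`` annotated recordings plus a grouped manifest to ``out_dir``.

    Recordings are assigned to synthetic subject/day groups of
    ``recordings_per_group`` consecutive recordings, giving grouped
    cross-validation something meaningful to split on.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} is not empty; pass overwrite=True to reuse it")
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, cfg in enumerate(_spawned_configs(config, n)):
        rec, labels = generate_recording(cfg)
        rec_id = f"synth_{i:05d}"
        wav_path = out_dir / f"{rec_id}.wav"
        lab_path = out_dir / f"{rec_id}_label.txt"
        rec.id = rec_id
        write_wav(rec, wav_path)
        write_labels(labels, lab_path)
        rows.append({
            "id": rec_id,
            "wav_path": str(wav_path),
            "label_path": str(lab_path),
            "group": f"day{i // recordings_per_group:04d}",
            "duration_s": rec.duration_s,
        })
    manifest = Manifest.build(rows)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
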