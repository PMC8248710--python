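"""Feature pipeline: 15-s recording -> 938 x 193 normalized feature matrix.

Stages, applied to the 4-kHz signal:

1. 10th-order Butterworth high-pass at 80 Hz, run forward-backward
   (zero-phase) so event onsets are not shifted relative to the labels.
   This removes mains interference and part of the heart-sound energy.
2. STFT with a 256-point Hann window and hop 64 (no FFT zero-padding
   beyond the window), center-padded so a 60,000-sample signal yields
   exactly ``1 + floor(60000/64) = 938`` frames of 129 bins
   (0..2000 Hz in 15.625-Hz steps).  Log magnitude is
   ``20*log10(|X| + 1e-10)``.
3. MFCC block: 40 triangular HTK-mel filters, 20 static coefficients
   (including c0), 20 deltas and 20 accelerations with regression
   width 9 -> 60 columns, on the same framing.
4. Band-energy sums of spectral power over 0-250, 250-500, 500-1000 and
   0-2000 Hz (bin-center membership, half-open bands; the last band
   spans the whole axis) -> 4 columns.
5. Concatenation (129 | 60 | 4 = 193 columns) and per-recording,
   per-column min-max normalization into [0, 1]; constant columns map
   to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.fft import dct, rfft

from .audio_io import Recording, STANDARD_SAMPLES

N_FFT = 256
HOP = 64
N_FRAMES = 938
N_SPEC_BINS = 129
N_MELS = 40
N_MFCC = 20
DELTA_WIDTH = 9
N_FEATURES = 193
FRAME_STEP_S = HOP / 4000.0          # 0.016 s
BIN_HZ = 4000.0 / N_FFT              # 15.625 Hz
LOG_EPS = 1e-10

BAND_EDGES_HZ = ((0.0, 250.0), (250.0, 500.0), (500.0, 1000.0), (0.0, 2000.0))


@dataclass
class Spectrogram:
    """Log-magnitude STFT: 938 frames x 129 bins with explicit axes."""

    values: np.ndarray               # (938, 129) dB-like log magnitude
    freq_axis: np.ndarray            # bin centers, Hz
    time_axis: np.ndarray            # frame centers, s

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.time_axis), len(self.freq_axis)):
            raise ValueError("spectrogram axes inconsistent with value matrix")

    @property
    def linear_power(self) -> np.ndarray:
        """Per-bin spectral power (squared linear magnitude)."""
        mag = 10.0 ** (self.values / 20.0) - LOG_EPS
        return np.maximum(mag, 0.0) ** 2


@dataclass
class FeatureMatrix:
    """938 x 193 normalized features: [spectrogram | MFCC(+d,+dd) | band energies]."""

    values: np.ndarray

    SPEC_SLICE = slice(0, 129)
    MFCC_SLICE = slice(129, 189)
    BAND_SLICE = slice(189, 193)

    def __post_init__(self) -> None:
        if self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must have {N_FEATURES} columns, got {self.values.shape[1]}")


def highpass(rec: Recording, order: int = 10, cutoff_hz: float = 80.0) -> Recording:
    """Zero-phase Butterworth high-pass filter."""
    nyquist = rec.sample_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist} Hz")
    sos = sp_signal.butter(order, cutoff_hz, btype="highpass",
                           fs=rec.sample_rate, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, rec.samples)
    return Recording(samples=filtered, sample_rate=rec.sample_rate,
                     id=rec.id, source=rec.source)


def _frame_signal(samples: np.ndarray) -> np.ndarray:
    """Center-padded framing: (938, 256) windowed frames."""
    if samples.shape[0] != STANDARD_SAMPLES:
        expected = 1 + STANDARD_SAMPLES // HOP
        raise ValueError(
            f"expected {STANDARD_SAMPLES} samples ({expected} frames); "
            f"got {samples.shape[0]}")
    padded = np.pad(samples, N_FFT // 2)
    idx = np.arange(N_FRAMES)[:, None] * HOP + np.arange(N_FFT)[None, :]
    return padded[idx]


_WINDOW = sp_signal.get_window("hann", N_FFT, fftbins=True)


def _stft_magnitude(samples: np.ndarray) -> np.ndarray:
    frames = _frame_signal(samples) * _WINDOW
    return np.abs(rfft(frames, n=N_FFT, axis=1))


def stft_logspec(rec: Recording) -> Spectrogram:
    """Log-magnitude spectrogram, exactly 938 x 129 for a 15-s input."""
    mag = _stft_magnitude(rec.samples)
    values = 20.0 * np.log10(mag + LOG_EPS)
    freq_axis = np.arange(N_SPEC_BINS) * BIN_HZ
    time_axis = np.arange(N_FRAMES) * FRAME_STEP_S
    return Spectrogram(values=values, freq_axis=freq_axis, time_axis=time_axis)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int = N_MELS, fmin: float = 0.0,
                    fmax: float = 4000.0) -> np.ndarray:
    """Triangular HTK-mel filters on the 129 rfft bin centers.

    The nominal band extends to 4 kHz; filters whose support lies above
    the 2-kHz Nyquist therefore receive no energy and produce constant
    (floor) log outputs, which the later normalization maps to zero and
    the delta regressions ignore.
    """
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bin_freqs = np.arange(N_SPEC_BINS) * BIN_HZ
    fb = np.zeros((n_mels, N_SPEC_BINS))
    for m in range(n_mels):
        lo, center, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bin_freqs - lo) / max(center - lo, 1e-9)
        down = (hi - bin_freqs) / max(hi - center, 1e-9)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


_MEL_FB = _mel_filterbank()


def _delta(x: np.ndarray, width: int = DELTA_WIDTH) -> np.ndarray:
    """Regression-based delta over ``width`` frames with edge replication."""
    half = width // 2
    denom = 2.0 * sum(n * n for n in range(1, half + 1))
    padded = np.pad(x, ((half, half), (0, 0)), mode="edge")
    out = np.zeros_like(x)
    for n in range(1, half + 1):
        out += n * (padded[half + n:half + n + x.shape[0]]
                    - padded[half - n:half - n + x.shape[0]])
    return out / denom


def mfcc_block(rec: Recording) -> np.ndarray:
    """938 x 60 block: 20 static MFCCs (incl. c0), 20 deltas, 20 accelerations."""
    power = _stft_magnitude(rec.samples) ** 2
    mel_power = power @ _MEL_FB.T
    log_mel = np.log(mel_power + LOG_EPS)
    cepstra = dct(log_mel, type=2, axis=1, norm="ortho")[:, :N_MFCC]
    d1 = _delta(cepstra)
    d2 = _delta(d1)
    return np.concatenate([cepstra, d1, d2], axis=1)


def band_energy(spec: Spectrogram) -> np.ndarray:
    """938 x 4 spectral-power sums over the four diagnostic bands.

    Band membership is by bin-center frequency with half-open intervals
    [lo, hi); the final 0-2000 Hz band covers the full axis (all bins,
    including the 2000-Hz bin) so it dominates the three sub-bands.
    """
    power = spec.linear_power
    out = np.zeros((power.shape[0], len(BAND_EDGES_HZ)))
    for b, (lo, hi) in enumerate(BAND_EDGES_HZ):
        if (lo, hi) == (0.0, 2000.0):
            mask = np.ones_like(spec.freq_axis, dtype=bool)
        else:
            mask = (spec.freq_axis >= lo) & (spec.freq_axis < hi)
        out[:, b] = power[:, mask].sum(axis=1)
    return out


def minmax_normalize(matrix: np.ndarray) -> np.ndarray:
    """Independent per-column min-max scaling to [0, 1]; constant columns -> 0."""
    lo = matrix.min(axis=0, keepdims=True)
    hi = matrix.max(axis=0, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0
    return (matrix - lo) / span


def assemble_features(spec: Spectrogram, mfcc: np.ndarray,
                      bands: np.ndarray) -> FeatureMatrix:
    """Concatenate the three blocks and min-max normalize each column."""
    n = spec.values.shape[0]
    if mfcc.shape[0] != n or bands.shape[0] != n:
        raise ValueError(
            f"frame-count mismatch: spectrogram {n}, MFCC {mfcc.shape[0]}, "
            f"bands {bands.shape[0]}")
    raw = np.concatenate([spec.values, mfcc, bands], axis=1)
    return FeatureMatrix(values=minmax_normalize(raw))


def extract_features(rec: Recording, *, order: int = 10,
                     cutoff_hz: float = 80.0) -> tuple[FeatureMatrix, Spectrogram]:
    """Full pipeline: high-pass -> STFT/MFCC/bands -> normalized matrix.

    Returns the feature matrix together with the (pre-normalization)
    spectrogram, which postprocessing reuses for energy-peak estimation.
    """
    filtered = highpass(rec, order=order, cutoff_hz=cutoff_hz)
    spec = stft_logspec(filtered)
    mfcc = mfcc_block(filtered)
    bands = band_energy(spec)
    return assemble_features(spec, mfcc, bands), spec
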