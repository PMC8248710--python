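"""From a 15-s recording to the 938 x 193 normalized feature matrix.

The pipeline high-pass filters at 80 Hz (10th-order Butterworth,
zero-phase), takes an STFT with a 256-point Hann window and hop 64
(938 frames x 129 bins, 15.625 Hz/bin, 16 ms/frame), adds 20 MFCCs with
deltas and accelerations (60 columns) and four band-energy sums, then
min-max normalizes each column into [0, 1].
"""

import numpy as np

from lungsed import SynthConfig, extract_features, generate_recording

rec, labels = generate_recording(SynthConfig(seed=7))
features, spectrogram = extract_features(rec)

print(f"recording: {rec.n_samples} samples at {rec.sample_rate} Hz "
      f"({rec.duration_s:.0f} s), {len(labels)} labeled events")
print(f"spectrogram: {spectrogram.values.shape} "
      f"(frames x bins), bin width {spectrogram.freq_axis[1]:.3f} Hz, "
      f"frame step {spectrogram.time_axis[1]*1000:.0f} ms")
print(f"feature matrix: {features.values.shape}, "
      f"range [{features.values.min():.1f}, {features.values.max():.1f}]")

# the inhalation frames carry visibly more mid-band energy than silence
from lungsed import events_to_frames
target = events_to_frames(labels, "I")
band2 = features.values[:, 190]  # normalized 250-500 Hz band energy
print(f"mean 250-500 Hz band energy: "
      f"{band2[target.values == 1].mean():.3f} inside inhalations vs "
      f"{band2[target.values == 0].mean():.3f} outside")
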