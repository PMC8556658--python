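"""Differential-entropy features from raw epoched signals.

Builds a small synthetic cohort whose sleep stages differ by their dominant
EEG rhythm, extracts band-wise differential entropy per channel and epoch,
and shows that the class-0 (slowest-rhythm) epochs carry most energy in the
delta band.
"""

import numpy as np

from sleepgcn.features import DEFAULT_BAND_NAMES, extract_de_features
from sleepgcn.synthetic import SyntheticSpec, generate_raw_cohort

spec = SyntheticSpec(n_subjects=1, epochs_per_subject=20, n_channels=4, seed=42)
rec = generate_raw_cohort(spec, sampling_rate=128.0)[0]
print(f"recording: {rec.signal.shape[0]} channels x {rec.signal.shape[1]} samples "
      f"x {rec.n_epochs} epochs at {rec.sampling_rate:g} Hz")

features = extract_de_features(rec)
print(f"feature matrices: {len(features)} epochs, each {features[0].values.shape} "
      f"(channels x bands {list(DEFAULT_BAND_NAMES)})")

first_class0 = int(np.where(rec.labels == 0)[0][0])
fm = features[first_class0]
print(f"\nepoch {first_class0} (stage 0, 2 Hz rhythm) DE per channel and band:")
for name, row in zip(rec.montage.names, fm.values):
    print(f"  {name}: " + "  ".join(f"{v:6.3f}" for v in row))
print("-> the first (delta) column is the largest entry of every row: the "
      "dominant rhythm of the stage shows up directly in the DE features.")
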