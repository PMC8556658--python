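"""Interpretability exports: attention summaries and per-stage graphs.

Trains briefly, then averages the temporal-attention centre row and the
spatial-attention column sums over correctly classified windows, and the
learned adjacency per stage - the standard inspection tables.
"""

import numpy as np

from sleepgcn.features import STAGE_NAMES, Standardizer
from sleepgcn.io import summarize_attention
from sleepgcn.model import ModelConfig, build_model
from sleepgcn.synthetic import SyntheticSpec, cohort_windows, generate_cohort

spec = SyntheticSpec(n_subjects=3, epochs_per_subject=100, n_channels=6, seed=4)
recordings = generate_cohort(spec)
windows = cohort_windows(recordings, d=2)
std = Standardizer().fit(windows).transform(windows)

config = ModelConfig(epochs=30, seed=0, patience=0, val_fraction=0.0)
model = build_model(config, recordings[0].montage, n_domains=3).fit(std)
pred = model.predict(std)
y = np.array([w.label for w in std])

summary = summarize_attention(pred, y, view="fc")
d = (len(summary["temporal"]) - 1) // 2
print("temporal attention of the centre epoch over its context window:")
for off, w in zip(range(-d, d + 1), summary["temporal"]):
    print(f"  epoch {off:+d}: {w:.3f}")
print("-> how much each context epoch contributes when classifying the centre.")

print("\nmean learned adjacency per stage (row sums of A_fc, first 3 channels):")
for c, stage in enumerate(STAGE_NAMES):
    mask = y == c
    if mask.any():
        A = pred["A_fc"][mask].mean(axis=0)
        print(f"  {stage}: {np.round(A[0, :3], 3)} ...")
print("-> one row-stochastic functional-connectivity graph per stage, the "
      "per-stage export used to inspect what the graph learner found.")
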