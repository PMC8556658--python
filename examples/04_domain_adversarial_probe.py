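"""How adversarial training removes subject identity from the features.

Trains the same model twice on a cohort with strong subject-specific
offsets - once with the gradient-reversal domain head active, once with it
inert (beta = 0) - then fits a fresh logistic probe on the frozen fused
features to predict *which subject* each window came from.

The adversarial run keeps a constant reversal strength from the first step
(auto-balancing off): subject information must be suppressed before the
label task consolidates, otherwise the adversary merely confuses its own
head while a fresh probe still decodes the subject.
"""

from sleepgcn.evaluation import domain_probe_accuracy
from sleepgcn.features import Standardizer, windows_to_array
from sleepgcn.model import ModelConfig, build_model
from sleepgcn.synthetic import SyntheticSpec, cohort_windows, generate_cohort

spec = SyntheticSpec(n_subjects=8, epochs_per_subject=100)
recordings = generate_cohort(spec)
windows = cohort_windows(recordings, d=2)
std = Standardizer().fit(windows).transform(windows)
_, y, subjects = windows_to_array(std)

for beta, epochs in ((0.8, 200), (0.0, 40)):
    config = ModelConfig(
        epochs=epochs, seed=3, beta=beta, grad_clip=1.0, adaptive_beta=False,
        domain_label_smoothing=0.1, patience=0, val_fraction=0.0,
    )
    model = build_model(config, recordings[0].montage, n_domains=spec.n_subjects)
    model.fit(std)
    probe = domain_probe_accuracy(model.extract_features(std), subjects, seed=0)
    label_acc = (model.predict(std)["labels"] == y).mean()
    print(f"beta = {beta}: subject-probe accuracy {probe['accuracy']:.3f} "
          f"(chance {probe['chance']:.3f}), stage accuracy {label_acc:.3f}")
print("-> with the adversary on, the probe falls close to chance while the "
      "stage accuracy stays high; with it off, subject identity is "
      "trivially decodable. That difference is what 'subject-invariant "
      "features' means operationally. (The equilibrium is seed- and "
      "scale-sensitive; see the methods note.)")
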