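# Methods

## Problem and model

`sleepgcn` classifies 30-second epochs of multi-channel neurophysiological
recordings into the five AASM sleep stages (Wake, N1, N2, N3, REM).  Each
epoch is summarised per channel by differential entropy (DE) in a set of
frequency bands, and each classification decision sees a temporal context
window of `Tn = 2d + 1` consecutive epochs centred on the epoch to label.

The classifier is a two-branch spatial-temporal graph network over the
electrode montage:

* **Functional-connectivity (FC) view.**  The adjacency is *learned* per
  window from the centre epoch's feature matrix:
  `A[m,n] = softmax_n( ReLU( w^T |x_m - x_n| ) )`, with a learnable weight
  vector `w` (one weight per feature).  A graph-learning loss
  `sum_{m,n} ||x_m - x_n||^2 A[m,n] + lambda ||A||_F^2` (default
  `lambda = 0.001`) is added to the training objective (weight `gamma`,
  default `1e-4`) so strong edges connect similar nodes and the graph stays
  sparse.
* **Distance (DC) view.**  A fixed adjacency from electrode geometry:
  a Gaussian kernel `exp(-dist^2 / 2 sigma^2)` of pairwise Euclidean
  distance, hollow diagonal, entries below a threshold (default 0.1)
  removed.  `sigma` defaults to the mean pairwise distance.

Each branch applies temporal attention (a `Tn x Tn` row-stochastic map that
re-mixes the context epochs), spatial attention (an `N x N` row-stochastic
map over channels), a Chebyshev spectral graph convolution of order `K - 1`
whose polynomial terms are modulated elementwise by the spatial-attention
map, and a same-padded temporal convolution; ReLU activations throughout.
Branch outputs are concatenated channel-wise, flattened, and fed to an
affine-softmax stage head.

**Domain generalization.**  Every training subject is one source domain.
A domain head (64 hidden units, ReLU, affine-softmax) predicts the subject
from the same fused features, connected through a gradient reversal layer
(GRL): identity forward, gradient scaled by `-beta` backward.  Both heads
minimise cross-entropy; the reversal makes the trunk *maximise* domain
confusion, the saddle objective of domain-adversarial training.  The total
training loss is `L_y + L_d + gamma * L_graph`, with the adversarial sign
carried entirely by the GRL.

## Numerical and design choices

* **Autodiff.**  The model runs on a compact reverse-mode automatic
  differentiation core over float64 numpy arrays (`sleepgcn.autodiff`),
  validated op-by-op and end-to-end against central finite differences.
  Note that for parameters upstream of the GRL the correct reference
  objective is the reversed surrogate `L_y - beta L_d + gamma L_graph`.
* **Feature extractor.**  Zero-phase 4th-order Butterworth band-pass per
  band, then `DE = 0.5 ln(2 pi e var)`.  Default bands: delta 0.5–4,
  theta 4–8, alpha 8–13, sigma 13–16, beta 16–30 and gamma 30–45 Hz
  (`Fd = 6`).  Variances are floored (default `1e-12`) so silent channels
  stay finite.  Windows at the recording boundary (first/last `d` epochs)
  are dropped, never padded.
* **Laplacians.**  The spectral filter needs a symmetric Laplacian, so the
  row-softmaxed FC adjacency is symmetrised as `(A + A^T)/2`.  The
  standalone `scaled_laplacian` computes `lambda_max` exactly by dense
  eigendecomposition (montages are small); *inside* the model the learned
  graph uses the standard `lambda_max = 2` approximation (`L_tilde = L - I`)
  to avoid differentiating an eigendecomposition.  An all-zero graph falls
  back to `L_tilde = -I` with a warning.
* **Attention.**  Parameters initialise uniformly in `±1e-2` so initial
  maps are near-uniform; each view owns its own attention parameters.  With
  a zero output gain the map is exactly uniform (the bias sits inside the
  sigmoid, so it cannot leak through a zero gain).
* **Architecture defaults.**  One attention + graph-conv + temporal-conv
  block per view, `d = 2`, `K = 3`, 10 channels per block, `k_t = 3`;
  after fusion the tensor is flattened for the heads.  The ablation ladder
  (`ModelConfig.variant("a")` … `"e"`) stacks: DC graph conv → + temporal
  conv → + attention → + FC view/fusion → + domain generalization.
* **Optimisation.**  Adam, lr `1e-3`, batch 64, optional early stopping on
  a validation split of the training windows (patience 20).  Initialisation
  uses one fixed RNG stream per component, so enabling or disabling a
  component never shifts the initial values of the others; with `beta = 0`
  the training trajectory of the shared parameters is bit-identical to the
  no-DG ablation.
* **Stabilising the adversarial game.**  With a strong, trivially separable
  subject nuisance, vanilla GRL training has two failure modes: the domain
  head saturates (its gradient vanishes and subject information survives
  untouched) or, at large `beta`, the trunk falls onto the chance plateau
  (all losses at their `ln R` values) and may never escape.  The package
  exposes the standard stabilisers as configuration: label smoothing on the
  domain loss (keeps the adversarial gradient alive once the head is
  confident; default 0.1), per-group gradient-norm clipping (default 5.0),
  a separate Adam instance for the domain head, and an *auto-balancing*
  rule (on by default): while the epoch-mean label loss sits above 1.2 —
  i.e. near the five-class chance plateau — the effective `beta` is halved
  each epoch, and once it recovers below 0.6 the strength is restored
  toward its configured value.  Escape from the plateau is otherwise
  stochastic: identical configurations train to high accuracy on one
  training set and stick at chance on another.  Auto-balancing trades
  scrub depth for reliability: backing `beta` off during the plateau lets
  the label task consolidate first, after which the adversary confuses its
  own head more than it removes subject information; constant-`beta` runs
  that avoid the plateau reach substantially deeper invariance (see
  `examples/04_domain_adversarial_probe.py`), at the risk of folds that
  never escape it.  A sigmoid `beta` warm-up
  and periodic domain-head re-initialisation are also available but off by
  default: in our experiments both prevent collapse *and* prevent genuine
  information removal (once label features consolidate, the adversary only
  hides subject information from the trained head; a fresh probe still
  decodes it).  Clipping is computed per parameter group (trunk+label head
  vs. domain head) so an inert `beta = 0` domain head cannot perturb the
  main update.
* **Metrics.**  Accuracy, per-class F1 (0 when precision+recall is 0),
  macro-F1 averaged over classes present in the truth, and Cohen's kappa
  with marginal-product chance agreement (the single-cell degenerate case
  is defined as 1 for perfect agreement).  Cross-validation is
  subject-independent: folds partition subjects (shuffled by seed, dealt
  round-robin), and standardisation statistics are fit on training subjects
  only.  Headline numbers pool predictions over folds; per-fold mean ± sd
  is also reported.

## The synthetic cohort

`SyntheticSpec` generates multi-subject cohorts directly in feature space:
stage labels follow a first-order Markov chain with stay-probability `rho`
(default 0.7) and uniform switching; epoch features are
`delta * M_class + eta * U_subject + coloured noise`, where `M_class` is a
per-class pattern shared by all subjects, `U_subject` a per-subject offset
(both standard-normal draws), `delta = 2.0` and `eta = 1.5` in units of the
unit-variance noise.  Noise is mixed across channels so that the empirical
channel correlation converges to `0.5 (I + D^{-1/2} A D^{-1/2})` (rescaled
to unit diagonal) for the ground-truth graph `A` — a ring by default, so
physical neighbours correlate.  A raw-waveform variant gives each stage a
dominant rhythm (2, 6, 10, 14.5, 22 Hz) with channel-specific amplitudes,
exercising the DE extractor end-to-end.  Everything is a pure function of
the spec; identical specs give byte-identical cohorts.

What the generator does *not* emulate: real PSG waveform morphology
(spindles, K-complexes), artifacts, class imbalance as severe as clinical
N1 scarcity, non-stationary drift within a night.  Passing the synthetic
recovery tests therefore demonstrates that the machinery (graph learning,
attention, spectral filtering, adversarial invariance, leakage-free CV)
works as specified — not that clinical-grade staging accuracy would be
reached on real recordings.

## Reference experiments and problem sizes

The canonical protocols live in `sleepgcn.experiments` and are shared by
the test suite and `scripts/acceptance.py`:

* **LOSO staging** on the fixed reference cohort (8 subjects × 400 epochs,
  `delta = 2.0`, `eta = 1.5`, cohort seed 20240101): leave-one-subject-out
  cross-validation of the full model with the reference training recipe
  (`beta = 1.5` with auto-balancing, domain label smoothing 0.2, gradient
  clip 1.0, 120 epochs, no early stopping).
* **Probe contrast**: the same model trained on all eight subjects, then a
  fresh logistic regression on the frozen fused features predicting the
  subject, with the adversary on versus `beta = 0`.
* **Ablation ladder**: variants b, d, e over five seeds on a cohort with
  the reference cohort's subject count and effect sizes but 80 epochs per
  subject, trained for 60 epochs, each run holding out one subject.  The
  reduction keeps the 15 training runs tractable on one CPU; the subject
  count is kept at 8 because with very few training subjects every added
  component overfits, confounding the component comparison.

These problem sizes are the package's reference settings; the qualitative
behaviour, not a benchmark number, is the object of interest.

## Known limitations

* The adversarial equilibrium is sensitive to `beta` and to the stabiliser
  settings; the defaults were chosen for the synthetic cohort family and
  will need re-tuning for data with a different nuisance-to-signal ratio.
* On this synthetic family, subject invariance and transfer accuracy trade
  off: the subject offsets and class patterns are random, overlapping
  directions of feature space, so scrubbing that truly removes the offset
  directions also distorts class-relevant directions.  Recipes that drive
  the subject probe toward chance cost several points of held-out accuracy
  relative to a `beta = 0` model; gentle reversal leaves subject identity
  linearly decodable.  Real recordings, where subject variation is not a
  clean linear offset, need not behave the same way.
* Because the generator's class signal is a per-class mean shift with
  class-independent channel correlation, the adaptive FC graph and the
  attention maps have no class-dependent connectivity structure to exploit;
  on such cohorts they add estimation variance without predictive benefit,
  and the plain distance-view network can outscore the full model.  These
  components earn their keep only on data whose connectivity carries class
  information.
* The learned FC adjacency is row-stochastic and hence asymmetric; its
  symmetrisation before the Laplacian is a modelling choice, and other
  choices (e.g. `max(A, A^T)`) would change the filter slightly.
* The EDF reader and standard 10-20 montage lookup require the optional
  `mne` dependency and load whole recordings into memory.
* Training is single-device, float64, CPU-oriented; the engine is not
  intended for montages beyond a few dozen channels.
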