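# Methods

## Problem setup

Input to every model is a 30-minute CGM history sampled every 5 minutes —
7 consecutive glucose values, scaled by 0.01 so model-facing values are
O(1) — and the target is the reading one prediction horizon (5–60 min,
multiples of 5) after the last input sample. Class labels derive from the
unscaled target: hypoglycemia strictly below 80 mg/dL, hyperglycemia
strictly above 180 mg/dL, normoglycemia on the closed band [80, 180]. The
80 mg/dL operational threshold (rather than the clinical 70 mg/dL level-1
definition) absorbs the ~10 mg/dL underestimation of hypoglycemia depth by
real-time CGM; `apply_cgm_artifact` reproduces that artifact for synthetic
data so the offset's rationale can be exercised in tests.

### Preprocessing

* **Grid snapping.** Timestamps are snapped to a 5-min grid anchored at the
  first sample; a sample deviating more than 90 s from its nearest grid
  point is treated as missing. Missing grid points are flagged, never
  imputed.
* **Smoothing.** A centered moving median (window 3 samples, configurable)
  removes isolated spikes, e.g. from patient movement, without introducing
  lag; missing samples are excluded from each window, and edge positions
  whose full window does not fit are left unchanged. A median was chosen
  over a moving average because it removes single-sample spikes exactly
  while leaving genuine trends untouched.
* **Windowing.** Sliding windows advance by one sample (5 min) by default,
  giving maximally overlapping segments. Any candidate whose input window
  or target touches a gap is discarded.
* **Splitting.** The target patient's train/test split is chronological:
  the first *n* segments train, and test segments must start after the last
  training target so no raw sample is shared across the boundary. A random
  split would leak information through overlapping windows.

## Architectures

All models share a two-group parameter layout — `feature_block` (the
sequence encoder) and `fnn_block` (tanh MLP of width 10 plus a linear
head) — which is the unit of transfer: strategies freeze, reuse, or
reinitialize whole groups, and frozen groups are bit-identical before and
after fine-tuning.

* **RNN**: 2 stacked GRU layers, hidden size 10; the feature is the final
  hidden state of the top layer (pooling choice; the last state of a GRU
  already summarizes the window). FNN depth 1.
* **CNN**: scalar inputs are linearly embedded to width 10, a learned
  additive position embedding is added, and 4 gated convolutional units
  (kernel 4, causal left padding) with gated-linear-unit activation
  a ⊙ σ(b) and residual connections follow; the feature is the last
  position, which sees the whole window. FNN depth 3.
* **SAN**: embedding and position embedding as for the CNN, then 8
  single-head scaled dot-product self-attention units in a pre-norm
  residual layout (layer norm feeds each sublayer; the residual stream is
  normalized once at the top), each with a position-wise feed-forward
  sublayer; the feature is the mean over positions. FNN depth 4. Two
  numerical choices matter at this tiny width: the input projection uses a
  3× gain (a scalar input carries little variance, and without the boost
  the position embedding can drown the sample signal in a deep normalized
  stack), and pre-norm rather than post-norm keeps the raw signal on the
  residual path — with post-norm the head saw nearly sample-independent
  features and regressed to a constant.
* **FNN** baseline: a linear embedding of the 7 raw inputs followed by the
  width-10 depth-3 head.

Heads: regression (scalar), binary or three-class (softmax). Since
convolution and attention consume all positions simultaneously, the CNN and
SAN require the position embedding; constructing them without it is an
error. Position embeddings are learned (the sinusoidal alternative adds
nothing at length 7).

### Losses and training

Regression losses: MAE, MSE, REL_MAE = mean(|ŷ−y|/y), REL_MSE =
mean((ŷ−y)²/y²); relative losses require strictly positive targets (always
true for scaled glucose) and up-weight errors at low glucose, which is why
REL_MAE is the default for regression; classification heads use
cross-entropy. Optimization is Adam (β₁ = 0.9, β₂ = 0.999), learning rate
3·10⁻³, batch 64, 100 epochs by default, no early stopping. The rate was
chosen as the largest at which all four architectures train stably on
10-segment memorization probes; fine-tuning defaults to the same optimizer
with the rate reduced 10× and 50 epochs. All randomness (init, shuffling,
augmentation substreams) derives from integer seeds through a counter-based
`SeedSequence` scheme, so identical configs reproduce identical bits.

## Transfer learning

Pretraining pools every cohort patient except the target (the exclusion is
asserted on per-segment patient-id tags). The four strategies:

| name | feature block | FNN block |
| --- | --- | --- |
| Pretrain | reuse, frozen | reuse, frozen |
| Transfer1 | reuse, retrain | reuse, retrain |
| Transfer2 | reuse, frozen | reuse, retrain |
| Transfer3 | reuse, frozen | reinitialize, retrain |

`loocv_evaluate` runs the protocol per patient — pretrain excluding them,
apply the strategy, fine-tune on their first *n* segments, test on the
chronological remainder — and reports each metric's unweighted mean ±
population s.d. across patients. An OhioT1DM-style pooling variant (all
patients' training portions plus an earlier release's test portions, minus
the target's training portion) is provided for users of that dataset.

## Minority augmentation

A segment is minority iff its target BG is below the 80 mg/dL threshold.
For fold k, augmentation leaves majority segments bitwise untouched and
makes the minority exactly k× its size: originals plus (k−1) generated
copies (`repeat` duplicates exactly; `noise` adds zero-mean Gaussian noise
of the configured variance, interpreted in (mg/dL)², to the 7 inputs only —
the printed variances 5/10/50 are dimensionally ambiguous and are taken as
variances on the mg/dL scale, applied before the 0.01 rescaling; `mixup`
interpolates minority pairs with λ ~ Beta(α, α), one λ per synthetic
segment, parents drawn uniformly with i ≠ j; `timegan` samples a generative
model fitted to the minority sequences). Synthetic copies are redrawn each
epoch from epoch-indexed substreams unless the plan disables regeneration.
k = 1 (or method `none`) is always the identity. Degenerate training sets
degrade gracefully inside a plan: with fewer than 2 minority segments
(mixup) or fewer than 50 (TimeGAN) the epoch falls back to exact
repetition, which preserves the k-fold arithmetic; calling `mixup_augment`
or `timegan_fit` directly on such inputs is still an error.

The TimeGAN is a reduced-scale re-implementation of the three-phase
embedder/recovery + supervisor + adversarial design (GRU stacks, hidden 24,
3 layers, ≤2000 total iterations by default), trained on min-max-normalized
univariate sequences. Inside a training plan it is fitted once, lazily, on
8-step sequences — the 7 inputs followed by the target — because a segment
does not carry the samples between window and target (they may even be
missing while the segment is valid); `timegan_fit` itself accepts sequences
of any length for callers who extract full-resolution spans from the raw
series. Fewer than 50 minority sequences is an error that advises noise or
mixup instead. Instead of visual PCA/t-SNE checks, `timegan_validate`
compares real and synthetic sets quantitatively: per-dimension mean and
s.d. gaps standardized by the real s.d., plus a two-sample energy distance
normalized by the mean within-real pairwise distance; it flags failure at a
standardized mean gap above 1.0 or a normalized energy distance above 0.5.

## Metrics

Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP), specificity = TN/(TN+FP),
NPV = TN/(TN+FN), accuracy = (TP+TN)/total, F1 = harmonic mean of PPV and
sensitivity; three-class accuracy is the fraction of exactly correct labels.
One widely circulated printing of the accuracy formula reads
(TP+FN)/(TP+FN+TN+FP), which equals the positive prevalence and cannot
match any reported accuracy; the standard formula is used here and the
discrepancy is deliberately not adopted. Metrics with a zero denominator
are reported as NaN, never coerced to 0 or 1. AUROC is computed rank-based
(Mann–Whitney with midrank ties), one-vs-rest per label in the three-class
task; regression outputs are scored as binary hypoglycemia detection by
thresholding predictions and truths identically at 80 mg/dL (a value
exactly at the threshold is negative). Horizon comparisons use a paired
two-sided t-test by default (Wilcoxon signed-rank optional) with the
star convention *, **, *** at p ≤ 0.05, 0.01, 0.001.

## Synthetic cohorts

The generator is a documented stand-in for an access-restricted clinical
cohort, not a physiological glucose–insulin model. A trace is basal level
(default 130.6 mg/dL, per-patient lognormal jitter σ = 0.05) + circadian
sinusoid (amplitude 15 mg/dL, random phase) + meal pulses (Poisson 3/day,
double-exponential shape with 15-min rise and 60-min decay, amplitude
60 mg/dL with per-patient jitter — large enough to cross 180 mg/dL) +
hypoglycemic dips (Poisson 3/day, Gaussian shape σ = 25 min, trough
uniform on 50–70 mg/dL) + stationary AR(1) noise (s.d. 5 mg/dL, ρ = 0.7),
clipped to the 40–400 mg/dL sensor range, with 2% of samples dropped as
gaps. Recording lengths are lognormal with median 90 h and log-s.d. 0.54
(matched to an 82–170 h interquartile spread). At these defaults
hypoglycemia occupies roughly 4–7% of samples — a deliberate minority-class
design point; the true prevalence of the motivating cohort is unpublished,
so this is an assumption, not a measurement. What the generator does *not*
emulate: meal–insulin dynamics, exercise, sensor drift or compression
artifacts, and inter-day habit structure. Passing tests therefore
demonstrate correctness of the pipeline and the *direction* of method
effects under realistic imbalance, not clinical performance on real CGM
data.

## Scaled-down evaluation sizes

The bundled end-to-end study (`augmentation_sensitivity_study`) uses
10-patient cohorts of 48 h each, a 20-min horizon, CNN + Transfer2, 20
pretraining epochs, 250 target training segments, and pools hypoglycemia
confusion counts over 3 target patients per seed across 5 master seeds.
These sizes were chosen so the full study runs in minutes on one CPU while
leaving ~20–60 hypoglycemic test events per seed — enough for a stable
sensitivity comparison between mixup (k=2, α=2) and the unaugmented run.
The acceptance script's LOOCV cell (6 patients, 36 h, 15 epochs) is sized
the same way.

## Known limitations

* Purely data-driven: glucose history is the only predictor; no insulin,
  meal, exercise, or demographic channels (a deliberate scope choice; the
  segment container leaves room for static covariates as an extension).
* The TimeGAN at this scale produces distributionally plausible but not
  temporally rich samples; with few minority sequences, mixup or noise
  augmentation is the better-behaved choice.
* Whether three-class results should come from classification heads or
  thresholded regression is ambiguous in practice; both are provided
  (`head="three_class"` vs regression + `regression_to_labels`).
* Sensitivity estimates on small synthetic cohorts carry Monte-Carlo error
  of several percentage points; conclusions should rest on the multi-seed
  means, not single runs.
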