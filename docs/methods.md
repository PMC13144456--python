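# Methods

## Problem and model

`wescnv` classifies exon-centered whole-exome-sequencing (WES) windows into
no-call / deletion / duplication from read depth. Each window is 1002
consecutive genomic bins of capture depth covering an exon and its flanks,
plus the window's genomic start/end coordinates and chromosome. Copy-number
changes shift expected depth (≈0.5× for a heterozygous deletion, ≈1.5× for a
duplication), but capture depth is noisy and locus-biased, so the classifier
must combine the local depth *shape* with positional context.

The network takes two inputs per window:

1. a (1002, 3) tensor — min-max-normalized depth, plus the normalized start
   and end coordinates broadcast along the sequence;
2. a 24-dim chromosome one-hot (chr1–22, chrX, chrY; mitochondrial
   chromosome excluded).

The chromosome indicator passes through a 24-unit ReLU embedding, is
repeated at all 1002 positions and concatenated with the channel tensor into
a (1002, 27) joint input. Two strided same-padding 1-D convolutions (32
filters, kernel 5, stride 2 → length 501; then 64 filters, kernel 3, stride
2 → length 251; both ReLU) extract local depth patterns. Global average
pooling yields a 64-vector, projected to a 128-unit ReLU latent with dropout
0.3. A softmax *feature attention* layer computes weights
`w = softmax(W·latent + b)` over the 128 latent coordinates and rescales the
latent elementwise (`w ⊙ latent`), so features are reweighted by relative
importance while dimensionality is preserved. A 256/128-unit ReLU head
(dropout 0.3 each) and a 3-way softmax produce class probabilities. Total:
102,299 parameters (11,160 encoder + 91,139 head).

The attention formulation is the minimal one consistent with a "dense
softmax attention over the pooled latent": attending over convolutional
time-steps before pooling is a plausible alternative, deliberately not
implemented here (the post-pooling placement follows the architecture
diagram this design matches).

All tensor math, backpropagation and Adam are implemented directly in NumPy
(float32, im2col convolutions). Same-padding uses the ceiling convention:
output length = ceil(L / stride), zeros split `total//2` left.

### Masking

Padded or missing depth bins carry the sentinel −1 and keep it through
normalization, so the network sees a value no observed (normalized ∈ [0,1])
bin can take and learns the sentinel. No multiplicative mask is applied
inside the convolutions; the encoding-time sentinel is the masking
mechanism.

### Normalization

One global `DepthScaler` is fitted on the *training partition only* and
reused for validation, test, fine-tune and platform-shifted data — this
prevents leakage and matches how a deployed model must treat new cohorts.
Depth extrema are computed over non-masked tokens; start and end are
normalized independently, genome-wide. Out-of-range transform inputs are
clamped to [0, 1] (keeping −1 unambiguous); a degenerate range (max = min)
maps to 0, since a constant carries no information.

## Training protocol

- 70/30 class-stratified split of the labeled windows (per-class proportions
  preserved up to rounding).
- SMOTE with the "auto" strategy (every class oversampled to the majority
  count), k = 5 neighbors, seed 42, applied **after** the split and to the
  training side only — a stricter ordering than "rebalance then split",
  chosen to keep synthetic points out of validation. Interpolation happens
  in the flattened window space (1002×3 + 24 = 3030 dims), the only
  representation-free choice. SMOTE is implemented in this package
  (k-NN via scikit-learn `NearestNeighbors`, convex-combination synthesis).
- Adam, learning rate 0.001, sparse categorical cross-entropy, batch size
  256 (default), early stopping with patience 10 on validation loss, and
  the minimum-validation-loss checkpoint returned.

### Transfer learning

Fine-tuning freezes the convolutional encoder (embedding + convolutions;
bit-identical before/after, asserted by parameter hash) and retrains a
freshly initialized head — latent projection, attention, 256/128 ReLU
layers with 50% dropout, output layer — at learning rate 0.0002 with
patience 5. Because the encoder is frozen, its pooled 64-dim outputs are
computed once per window and cached, making head retraining cheap. SMOTE is
applied to the cached features of the expert training partition by default,
mirroring the pretraining imbalance handling.

## Synthetic cohorts

The simulator emulates the exon-window matrices the classifier consumes;
it generates depth profiles, not reads.

- **Noise family**: per-bin depth ~ negative binomial with mean
  `mean_depth × GC(t) × copy-ratio` and size (dispersion) 20 — overdispersed
  counts, the standard model for capture coverage. Default mean depth 80.
- **GC / capture bias**: a smooth per-locus sinusoid (amplitude 0.15,
  period 150–400 bins, random phase) multiplies the mean — a cheap stand-in
  for probe-capture unevenness.
- **Events**: copy-ratio 0.5 (deletion) / 1.5 (duplication) over a
  contiguous span covering 60% of the window, centered; the label is
  window-level, as in the target data.
- **Recurrence structure**: a fixed *capture grid* (locus coordinates and
  recurrent-locus roles) derives from `grid_seed`, so cohorts with
  different `seed` share the grid the way real cohorts share a capture
  design. `frac_del`/`frac_dup` (default 0.08 each) are *window-level* CNV
  probabilities — the expected fraction of windows labeled DEL/DUP — and
  the number of CNV loci is derived from them: a recurrent locus carries
  the same event class in a strict majority (55–85%) of samples, a private
  locus in exactly one sample, so under the defaults the 16% window rate
  is realized by ~89 recurrent plus ~89 private CNV loci (of 400).
  Recurrent roles are fixed in the grid; private loci are re-drawn per
  cohort from the null loci, which is what populates the Never stratum
  when a held-out cohort is scored against training locus frequencies.
- **Padding**: 5% of windows end in a −1 run (50–300 bins).
- **Platform shifts**: observed depths are multiplied by a scale factor and
  re-noised with Gaussian noise of sd `noise_scale × sqrt(depth)`; masks,
  coordinates and labels are untouched.

Default cohort size is 50 samples × 400 loci (20,000 windows). What the
simulator does **not** model: real capture coordinates, correlated noise
across neighboring exons, allele-specific dosage, mosaicism, batch effects
beyond the single multiplicative shift. Passing tests therefore demonstrate
that the architecture and protocol recover planted depth signal under
realistic overdispersion and recurrence structure — not performance on real
WES data.

## Evaluation

A 3×3 window-level confusion matrix (rows truth, columns prediction) feeds
one-vs-rest per-class precision, recall, F1 and specificity: a DEL predicted
as DUP is one FN for DEL and one FP for DUP. Aggregates are macro
(unweighted) class means; zero-denominator metrics return 0 with an explicit
degenerate flag. PR-AUC uses average precision (step summation, not
trapezoidal); ROC-AUC is one-vs-rest macro; log loss floors probabilities at
1e−15; Cohen's kappa comes from the marginals and MCC from the multiclass
covariance formulation. Probability-based metrics delegate to scikit-learn;
everything is cross-checked against brute-force oracles in the test suite.

**Recurrence strata**: true CNV windows in a test set are stratified by the
fraction of training samples in which their locus was labeled CNV:
Never = {0}, Rare = (0, 0.05], Often = (0.05, 0.5], Majority = (0.5, 1]
(half-open boundaries; loci unseen in training count as Never). Two recall
flavours are reported because the stratified-recall definition admits both:
`cnv_recall` requires the exact true class; `any_cnv_recall` forgives
DEL/DUP cross-calls.

**Locus-prior baseline**: a classifier seeing only normalized start/end and
the chromosome indicator (26 inputs, never a depth token — asserted by
construction), trained with the same head protocol (256/128 ReLU + dropout,
SMOTE, Adam, early stopping). On cohorts whose CNVs are private, coordinates
carry no usable signal, so the gap between this baseline and the full model
isolates the depth contribution.

**Platform robustness**: each shift setting perturbs the raw test depths,
re-normalizes with the training scaler, and re-scores; the identity shift
must reproduce the unshifted metrics exactly.

## Problem sizes and numerical choices

- Training runs in the tests and the acceptance script use the default
  50×400 cohort with `max_epochs` 6: validation loss on this task plateaus
  within 2–3 epochs (the depth signal is strong), and the
  minimum-validation-loss checkpoint rule makes longer runs redundant. The
  locus-prior comparison uses a 10×1200 private-CNV-only cohort
  (frac_del = frac_dup = 0.005, recurrent_fraction = 0: 120 private loci,
  one carrier each). CNV loci are deliberately sparse (10% of the grid):
  if most loci carry CNVs, coordinates acquire population-level signal and
  the baseline is no longer a negative control. The grid is large so the
  depth model sees enough distinct private loci (~84 in its training
  partition) to learn the event signature without any recurrence shortcut.
  Recall for both models is pooled over the validation partition and a
  fresh unseen cohort from the same configuration to stabilize the
  estimate (n ≈ 156 CNV windows).
- Ties in the hard-call argmax resolve to the lowest class index
  (no-call < DEL < DUP), a conservative convention.
- Prediction probabilities must sum to 1 ± 1e−6; attention and output
  softmax normalization are asserted at the same tolerance.
- All randomness flows through explicit seeds (simulation seed, grid seed,
  split/shuffle/dropout/SMOTE seeds); a single global seed fans out in the
  CLI.

## Known limitations

- The simulator's private events give few minority-class training examples
  per cohort; SMOTE interpolates them, which mixes coordinates of different
  loci — acceptable for rebalancing, but it means synthetic points are not
  biologically coherent windows.
- The NumPy implementation targets CPU; it is adequate for the cohort sizes
  here but not for hundreds of thousands of windows per epoch.
- Fine-tuning retrains the full head (including latent projection and
  attention); retraining only the final dense layers is a smaller, untested
  variant.
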