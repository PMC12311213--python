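# Methods

`lymphgraph` implements an ultrasound-deep-feature → patient-similarity-graph →
graph-convolutional-network (GCN) pipeline for predicting axillary lymph node
metastasis (ALNM) in breast cancer, together with a synthetic data generator
that stands in for the three private hospital cohorts the original study used.
This note records the models, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical decisions a
maintainer would want written down.

## The pipeline

1. **Image preparation** (`preprocessing`). B-mode frames are converted to
   grayscale (Rec.709 luminance; the conversion is not specified anywhere
   upstream, so the broadcast-standard weights were chosen), the annotated
   lesion bounding box is cropped with an 8-pixel margin (a small boundary of
   adjacent tissue carries information; the exact width is a free choice), and
   the crop is resized so its longer side is 224 with the shorter side padded
   symmetrically with black — aspect ratio is never distorted. Interpolation
   is bilinear. Bounding boxes are 0-based and half-open throughout.
   Augmentation (flips, random crop, ±15° rotation) is seeded and allowed on
   the training cohort only; `guard_no_validation_augmentation` turns any
   attempt to augment a validation cohort into a pipeline error.

2. **Deep features** (`backbones`). The reference extractor is a 50-layer
   bottleneck residual network (conv1 7×7/2 → 3×3/2 max-pool → stages of
   3/4/6/3 bottleneck blocks at widths 64/128/256/512 with 4× expansion) with
   the classification head removed; the globally average-pooled activation of
   the last stage is the 2048-dimensional feature vector. It is implemented
   forward-only in NumPy. Normalisation layers use the input's own
   per-channel spatial statistics, which keeps activations bounded at any
   depth without trained running averages; weights are He-normal draws from a
   seed. Pretrained weights can be supplied through the same
   `BackboneContract`, but nothing in the package requires them: the
   dimensionality and determinism contracts hold for any weights, and the
   pipeline's default input is a feature table, not images. `fine_tune`
   trains a temporary binary softmax head (Adam, cross-entropy, seeded
   mini-batches) on the frozen, internally z-scored backbone features and
   then discards it; backbone weights are never updated. Head-only tuning is
   a deliberate reduction: backpropagating through the full 50-layer NumPy
   network is out of scope, and no package contract depends on it.

3. **Feature selection** (`selection`). Features are z-scored with training
   statistics (zero-variance columns get scale 1 and a logged warning). Pairs
   with |Spearman ρ| > 0.85 are redundant; the later-indexed member of each
   violating pair is dropped — a deterministic, order-stable rule, and rank
   correlation makes the filter invariant to monotone column transforms.
   Survivors go through recursive feature elimination under a linear SVM
   (C = 1): at each count the features with smallest |weight| are removed and
   mean accuracy under 10-fold stratified cross-validation is recorded; the
   returned subset is the accuracy-optimal count (ties toward fewer
   features), never below 3. Elimination drops 64 columns per step down to
   256 remaining, then one per step: single-column elimination from 2048
   columns costs ~2000 SVM fits for no measurable change in the final subset
   near the optimum. `n_features=22` skips the CV search and eliminates
   straight to a fixed 22-column subset, reproducing the study's 24-column
   node-table geometry (22 features + id + label); this is the default
   experiment configuration. Selection is fitted on the training cohort
   only; the frozen `SelectionResult` (JSON-serialisable) transforms any
   cohort without touching its labels.

4. **Graph construction** (`graph`). One graph per cohort: patients are
   nodes, and an undirected edge joins two patients when the cosine
   similarity of their selected standardized feature vectors is ≥ the
   threshold (inclusive; ties at the threshold are edges). Thresholds 0.60 /
   0.70 / 0.80 / 0.95 each define one model. Negative similarities (possible
   after z-scoring) are simply sub-threshold; no absolute value is taken.
   Isolated nodes are retained — the self-loop in Ã = A + I keeps the
   propagation operator P = D̃^(−1/2) Ã D̃^(−1/2) well defined, and every
   patient must be classified. Edges never cross cohorts.

5. **GCN** (`gcn`). Two graph-convolution layers (widths 64/32) with ReLU,
   dropout (rate 0.5) on the second layer's output, and a dense softmax head:
   H¹ = ReLU(P X W⁰), H² = ReLU(P H¹ W¹), Z = softmax(H² W^fc). No bias
   terms, matching the propagation rule as written. Hidden widths, dropout
   rate and patience are unstated upstream; 64/32 and 0.5 are conventional
   defaults for graphs of this size. Initialisation is seeded
   Glorot-uniform. Training is Adam at learning rate 1e-4 for up to 500
   epochs with cross-entropy. The graph is indivisible, so the stated batch
   size of 32 is honoured by mini-batching the *loss*: each gradient step
   runs the full-graph propagation but takes the cross-entropy over a
   32-node batch of training nodes, giving ⌈n/32⌉ steps per epoch
   (`batch_size=0` gives classical full-batch steps). A stratified 15% of
   training nodes is excluded from the loss and monitored for early stopping
   (patience 50, best-epoch weights returned); monitoring an internal mask
   rather than the external validation cohorts avoids model-selection
   leakage, at the price of 15% of the training labels. Training is
   bit-reproducible given a seed. Validation inference runs the trained
   weights on each validation cohort's own graph.

6. **Evaluation** (`evaluation`). Threshold metrics (accuracy, sensitivity,
   specificity, PPV, NPV) at a 0.5 default cutoff, each with a stratified
   percentile-bootstrap 95% CI (2000 replicates; cases are resampled within
   label class, degenerate resamples are skipped and counted). NPV is
   TN/(TN+FN); the FN/(FN+TN) variant that circulates in one printed
   rendering of the formula is a typographical slip — it is 1 − NPV — and is
   available only behind `printed_npv=True` for audit. AUC is the
   tie-corrected Mann–Whitney statistic. Paired AUCs are compared with the
   DeLong test (per-case structural components via midranks; covariance of
   the paired components; two-sided normal p; p = 1 by convention when the
   variance of an exactly-zero difference vanishes). Decision-curve analysis
   reports net benefit NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) on a 0.01–0.99
   grid against treat-all and treat-none. Model agreement is pairwise
   Pearson r of predicted probabilities; repeated-measures ANOVA (patients
   as subjects, models as the within-subject factor; df = (k−1), (k−1)(n−1))
   is the primary across-model test, with one-way ANOVA available for
   comparison.

## The synthetic generator

The real cohorts (621 training, 112 and 87 external validation; metastasis
prevalences 0.346 / 0.402 / 0.402) are private. `synthetic` draws stand-in
cohorts from a class-conditional equal-covariance Gaussian model chosen
because its Bayes-optimal AUC is available in closed form,
Φ(Δ/√2) for Mahalanobis class separation Δ, which gives every downstream
accuracy claim an exact reference. Defaults: 2048 feature columns of which
22 are informative (matching the study's selected-feature count, with the
class-mean difference spread evenly so Δ = 2.0 and Bayes AUC ≈ 0.921), 61
are redundant copies — a signed linear transform of an informative partner
plus noise calibrated through the Gaussian rank-correlation identity
ρ_s = (6/π)·asin(ρ_p/2) so the pair's Spearman correlation is 0.95 in
expectation, making the 2048 → ~1987 redundancy-filter geometry of the study
reproducible — and the rest are standard normal noise. Column roles are
randomly permuted; all three cohorts share one permutation, partner map and
coupling signs, so selectors fitted on the training cohort transfer.
Labels are Bernoulli draws at the cohort prevalence.

What the generator does *not* emulate: real deep-feature distributions are
not Gaussian and have never been characterised for this task; there is no
scanner/vendor effect, no cohort shift (a `mean_shift` knob exists and
defaults to 0), no label noise beyond class overlap, and no
clinicopathological covariates. Passing tests therefore certify the
pipeline's mechanics and its statistical machinery under a known model —
not clinical performance on real ultrasound data.

Toy lesion images (`generate_toy_images`) are speckled Rayleigh backgrounds
with one dark ellipse; positive lesions are larger with irregular
(sinusoidally wobbled) margins, so shape/size-sensitive extractors have
honest signal. They exist to exercise preprocessing and extraction end to
end, not to resemble clinical ultrasound.

## Numerical choices and degenerate inputs

- Cosine similarity rejects zero-norm rows by patient id; the diagonal is
  set to exactly 1 and values are clipped to [−1, 1] against rounding.
- `normalize_adjacency` validates symmetry, zero diagonal and 0/1 entries;
  an isolated node's row is exactly the standard basis vector.
- Sparse propagation is used for graphs above 200 nodes (the operator is
  typically very sparse at the study thresholds); dense below.
- Softmax is computed with the row-max subtracted; cross-entropy adds 1e-12
  inside the log. Early-stopping improvement must exceed 1e-12.
- CV accuracy ties in RFECV resolve toward fewer features; the RFE weight
  sort is stable, so equal-weight ties drop the lower-indexed column first.
- Metrics with empty denominators return NaN rather than raising; bootstrap
  replicates where a metric is undefined are dropped and counted.
- The experiment's single seed fans out to stage seeds via
  `seed XOR crc32(stage_name)`, so any stage can be re-run in isolation;
  manifests record SHA-256 digests of every artifact, and re-running a
  config reproduces them byte for byte.

## Design choices where the design was genuinely open

- **Full-graph transduction with loss mini-batching** (above) rather than
  neighborhood sampling; sampling would change the model, not just the
  optimizer.
- **Internal early-stop mask** rather than monitoring the external
  validation cohorts; the literal protocol ("validation loss") would leak
  model selection into the reported external performance.
- **Pair-drop rule** in the redundancy filter (drop the later index) —
  any deterministic rule works; this one is stable under appending columns.
- **Cutoff 0.5** for confusion-matrix reports, exposed as `--cutoff`; the
  study reports thresholded metrics without naming its cutoff.
- **Percentile bootstrap** for CIs; the study's CI method is unstated. The
  acceptance suite verifies by simulation (n = 200 datasets) that coverage
  for sensitivity stays within 95 ± 3 points of nominal.

## Known limitations

- With 2048 candidate columns and 621 training rows, the CV-optimal RFECV
  count is unstable and tends to over-select (~100+ columns, most of them
  noise, measured on synthetic draws); the fixed 22-feature mode transfers
  better and is the default experiment configuration.
- Training accuracy does not saturate on the synthetic cohorts: at Δ = 2.0
  the Bayes accuracy is Φ(1) ≈ 0.84, and under the fixed optimizer budget
  (≤ 500 epochs at 1e-4) the network cannot memorize the ~16% of labels the
  Bayes rule itself gets wrong. Saturated training metrics on real data are
  consistent with features that were themselves fine-tuned on the training
  labels — an upstream effect the synthetic conditions deliberately exclude.
- The NumPy residual backbone is forward-only; fine-tuning updates a
  temporary head, never the trunk.
- Inference on a validation cohort uses that cohort's own graph, so adding
  or removing patients changes other patients' predictions (transductive
  semantics, as in the study design).
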